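"""Scenario orchestration: synthetic inputs → quantification → report bundles.

A scenario is a named, seeded end-to-end analysis. Each run writes CSV
tables, a JSON summary, plots, and a manifest (config + package version +
seed) into its output directory; the manifest plus the global seed
reproduce every artifact byte-for-byte.

Built-in scenarios:

``invasiveness_gradient``
    spheroid masks whose boundary ruffling grows with chamber distance →
    invasiveness index per spheroid + linear fit against distance
``track_migration``
    ischemic-like (persistent) vs well-nurtured-like (brownian) track
    ensembles → speeds, persistence, runners, MSD exponents, directionality
``cpm_conditions``
    the four Potts-model conditions → mixing/invasion metrics + pooled MSD
``ph_gradient``
    ratiometric two-channel gradient images with and without a consumer
    monolayer → calibrated pH-vs-distance profiles
``drug_gradient``
    drug-intensity decay profile → concentration-vs-distance estimate
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cpm, morphometry, synthgen, trackstats
from .core import GradientProfile, LabelMask
from .errors import ConfigError
from .io import write_labels, write_profile, write_sidecar, write_tracks


def child_seed(global_seed: int, stream: int) -> int:
    """Deterministic per-module seed derived from the global seed.

    Uses a seed sequence keyed by (global_seed, stream index) so modules
    draw from independent streams; result fits in 31 bits.
    """
    return int(np.random.SeedSequence([int(global_seed), int(stream)])
               .generate_state(1)[0] % (2**31))


def _require(config: dict, key: str):
    if key not in config:
        raise ConfigError(f"missing required config key '{key}'")
    return config[key]


def _plot(fig, out_dir: Path, name: str) -> None:
    fig.savefig(out_dir / name, dpi=120)
    import matplotlib.pyplot as plt

    plt.close(fig)


def _figure():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots()


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def invasiveness_gradient(seed: int, out_dir: Path, params: dict) -> dict:
    """Shape index of synthetic spheroids along the chamber axis.

    Ruffle amplitude grows linearly with distance from the opening,
    emulating the protrusive morphology of ischemic spheroids; the scenario
    measures the invasiveness index of each mask and fits it against
    distance.
    """
    n = int(params.get("n_spheroids", 12))
    max_d = float(params.get("axis_length_mm", 10.0))
    amp_slope = float(params.get("amplitude_per_mm", 0.03))
    radius = float(params.get("radius_px", 120))
    rows = []
    for i in range(n):
        d = max_d * (i + 0.5) / n
        spec = synthgen.ShapeSpec(
            radius_px=radius,
            ruffle_amplitude=min(amp_slope * d, 0.95),
            ruffle_modes=(5, 8),
            seed=child_seed(seed, 100 + i),
        )
        mask = synthgen.make_spheroid_mask(spec)
        idx = morphometry.invasiveness_index(mask)
        rows.append({"spheroid_id": i, "distance_mm": d,
                     "condition": "consumers",
                     "region": morphometry.classify_region(d),
                     "metric": "invasiveness", "value": idx})
        if i == 0:
            write_labels(mask, out_dir / "example_mask.tif", spec)
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "invasiveness.csv", index=False)
    fit = morphometry.gradient_fit(df["distance_mm"], df["value"])
    fig, ax = _figure()
    ax.scatter(df["distance_mm"], df["value"])
    xs = np.linspace(0, max_d, 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "--")
    ax.set_xlabel("distance to opening (mm)")
    ax.set_ylabel("invasiveness index")
    _plot(fig, out_dir, "invasiveness_vs_distance.png")
    return {
        "n_spheroids": n,
        "slope_per_mm": fit.slope,
        "intercept": fit.intercept,
        "pearson_r": fit.r,
        "p_value": fit.p_value,
    }


def track_migration(seed: int, out_dir: Path, params: dict) -> dict:
    """Migration statistics of ischemic-like vs well-nurtured-like tracks."""
    n_tracks = int(params.get("n_tracks", 450))
    n_steps = int(params.get("n_steps", 96))
    dt = float(params.get("dt_min", 15.0))
    step = float(params.get("step_scale_um", 2.0))
    ensembles = {
        "no_consumers": synthgen.WalkSpec(
            model="brownian", n_tracks=n_tracks, n_steps=n_steps, dt_min=dt,
            step_scale_um=step, seed=child_seed(seed, 200)),
        "consumers": synthgen.WalkSpec(
            model="persistent", n_tracks=n_tracks, n_steps=n_steps, dt_min=dt,
            step_scale_um=step,
            persistence_time_min=float(params.get("persistence_time_min", 90.0)),
            seed=child_seed(seed, 201)),
    }
    summary = {}
    for cond, spec in ensembles.items():
        ts = synthgen.make_tracks(spec)
        ts.condition = cond
        write_tracks(ts, out_dir / f"tracks_{cond}.csv", spec)
        per_track = pd.DataFrame({
            "track_id": [t.track_id for t in ts],
            "net_um": [trackstats.net_displacement(t) for t in ts],
            "path_um": [trackstats.path_length(t) for t in ts],
            "persistence": [trackstats.persistence(t) for t in ts],
            "mean_speed_um_min": [
                float(np.mean(trackstats.instantaneous_speeds(t))) for t in ts],
        })
        per_track.to_csv(out_dir / f"per_track_{cond}.csv", index=False)
        curve = trackstats.msd(ts)
        pd.DataFrame({"lag_min": curve.lag_min, "msd_um2": curve.msd_um2,
                      "n_pairs": curve.n_pairs}).to_csv(
            out_dir / f"msd_{cond}.csv", index=False)
        fit = trackstats.fit_msd_exponent(curve, trackset=ts,
                                          seed=child_seed(seed, 210))
        runners = trackstats.classify_runners(ts)
        vecs = trackstats.displacement_vectors(ts)
        test = trackstats.directional_test(vecs.angles, vecs.magnitudes,
                                           seed=child_seed(seed, 211))
        summary[cond] = {
            "n_tracks": len(ts),
            "msd_exponent": fit.exponent,
            "msd_ci": [fit.ci_low, fit.ci_high],
            "mean_persistence": float(np.nanmean(per_track["persistence"])),
            "runner_count": runners.count,
            "runner_fraction": runners.fraction,
            "rayleigh_p": test.rayleigh_p,
            "moore_p": test.moore_p,
        }
    fig, ax = _figure()
    for cond in ensembles:
        df = pd.read_csv(out_dir / f"msd_{cond}.csv")
        ax.loglog(df["lag_min"], df["msd_um2"], label=cond)
    ax.set_xlabel("lag (min)")
    ax.set_ylabel("MSD (um^2)")
    ax.legend()
    _plot(fig, out_dir, "msd.png")
    return summary


def cpm_conditions(seed: int, out_dir: Path, params: dict) -> dict:
    """Four Potts-model conditions: metrics, ordering, pooled MSD per type."""
    scale = params.get("scale", "desk")
    n_rep = int(params.get("n_replicates", 4))
    seeds = [child_seed(seed, 300 + i) for i in range(n_rep)]
    summary = {}
    for cond in cpm.CONDITIONS:
        results = cpm.run_replicates(cond, seeds, scale=scale)
        frames = []
        for s, res in zip(seeds, results):
            m = res.metrics()
            df = pd.DataFrame(m)
            df.insert(0, "replicate_seed", s)
            frames.append(df)
        pd.concat(frames).to_csv(out_dir / f"metrics_{cond}.csv", index=False)
        fit1 = cpm.pooled_msd_fit(results, cpm.TYPE_C1,
                                  seed=child_seed(seed, 310))
        fit2 = cpm.pooled_msd_fit(results, cpm.TYPE_C2,
                                  seed=child_seed(seed, 311))
        finals = [r.metrics() for r in results]
        summary[cond] = {
            "mixing_final": float(np.mean([m["mixing_index"][-1] for m in finals])),
            "invasion_C1_final": float(np.mean([m["invasion_C1"][-1] for m in finals])),
            "invasion_C2_final": float(np.mean([m["invasion_C2"][-1] for m in finals])),
            "msd_exponent_C1": fit1.exponent,
            "msd_ci_C1": [fit1.ci_low, fit1.ci_high],
            "msd_exponent_C2": fit2.exponent,
            "msd_ci_C2": [fit2.ci_low, fit2.ci_high],
            "border_contact": any(r.border_contact for r in results),
        }
        write_labels(LabelMask(results[0].snapshots[-1]),
                     out_dir / f"final_{cond}.tif")
    ranking = sorted(cpm.CONDITIONS,
                     key=lambda c: -summary[c]["invasion_C1_final"])
    summary["invasion_ranking"] = ranking
    return summary


def ph_gradient(seed: int, out_dir: Path, params: dict) -> dict:
    """Estimated extracellular pH along the chamber, ± consumer monolayer.

    With consumers, the medium acidifies with distance (pH 7.4 at the
    opening falling toward ~6.7 deep in the chamber); without consumers the
    profile stays flat. The scenario images both as two-channel ratio
    stacks, calibrates ratio→pH from titrated anchors, and recovers the
    profiles.
    """
    axis = float(params.get("axis_length_mm", 10.0))
    noise = float(params.get("noise_sd", 1.0))
    # calibration: green/blue ratio rises as the medium acidifies
    anchor_ph = np.array([6.4, 6.8, 7.2, 7.6, 8.0])
    anchor_ratio = np.array([2.0, 1.6, 1.2, 0.9, 0.7])
    curve = morphometry.calibrate_ph(anchor_ratio, anchor_ph)

    def ratio_for_ph(ph):
        return np.interp(ph, anchor_ph, anchor_ratio)

    d = np.linspace(0, axis, 41)
    profiles = {
        "consumers": 7.4 - 0.7 * (d / axis),
        "no_consumers": np.full_like(d, 7.4),
    }
    out = {}
    for cond, ph in profiles.items():
        target = GradientProfile(d, ratio_for_ph(ph), value_kind="ratio")
        img = synthgen.make_gradient_image(
            axis, target, noise_sd=noise,
            seed=child_seed(seed, 400 + len(out)))
        est = morphometry.estimate_ph_profile(img, curve)
        write_profile(est, out_dir / f"ph_profile_{cond}.csv")
        fit = morphometry.gradient_fit(est.distance_mm, est.value)
        out[cond] = {"slope_ph_per_mm": fit.slope, "pearson_r": fit.r,
                     "ph_at_opening": float(est.value[0]),
                     "ph_at_end": float(est.value[-1]),
                     "n_clamped": est.flags["n_clamped"]}
    fig, ax = _figure()
    for cond in profiles:
        df = pd.read_csv(out_dir / f"ph_profile_{cond}.csv")
        ax.plot(df["distance_mm"], df["value"], label=cond)
    ax.set_xlabel("distance to opening (mm)")
    ax.set_ylabel("estimated extracellular pH")
    ax.legend()
    _plot(fig, out_dir, "ph_profiles.png")
    return out


def drug_gradient(seed: int, out_dir: Path, params: dict) -> dict:
    """Drug concentration vs distance from fluorescent-analog intensity.

    The decay length is anchored so that relative intensity at 10 mm is
    0.30; with a 150 nM source this puts ~45 nM at 10 mm.
    """
    c0 = float(params.get("c0_nM", 150.0))
    axis = float(params.get("axis_length_mm", 14.0))
    anchor_d = float(params.get("anchor_distance_mm", 10.0))
    anchor_frac = float(params.get("anchor_fraction", 0.30))
    length_scale = -anchor_d / np.log(anchor_frac)
    profile = synthgen.make_decay_profile(c0, length_scale, axis, n_points=29)
    conc = morphometry.estimate_drug_concentration(profile, c0)
    write_profile(conc, out_dir / "drug_concentration.csv")
    at = lambda d: float(np.interp(d, conc.distance_mm, conc.value))
    fig, ax = _figure()
    ax.plot(conc.distance_mm, conc.value)
    ax.set_xlabel("distance to opening (mm)")
    ax.set_ylabel("estimated concentration (nM)")
    _plot(fig, out_dir, "drug_concentration.png")
    return {
        "c0_nM": c0,
        "length_scale_mm": length_scale,
        "conc_at_10mm_nM": at(10.0),
        "conc_at_12mm_nM": at(12.0),
        "monotonized": conc.flags.get("monotonized", False),
    }


SCENARIOS = {
    "invasiveness_gradient": invasiveness_gradient,
    "track_migration": track_migration,
    "cpm_conditions": cpm_conditions,
    "ph_gradient": ph_gradient,
    "drug_gradient": drug_gradient,
}


def run_scenario(config: dict) -> dict:
    """Execute a named scenario and write its report bundle.

    ``config`` requires ``scenario``, ``seed``, and ``out_dir``; scenario
    parameters go under ``params``. Returns the JSON-ready summary, which
    is also written to ``summary.json`` alongside a reproducibility
    manifest.
    """
    name = _require(config, "scenario")
    seed = int(_require(config, "seed"))
    out_dir = Path(_require(config, "out_dir"))
    params = config.get("params", {})
    if name not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = SCENARIOS[name](seed, out_dir, params)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
    manifest = {"scenario": name, "seed": seed, "params": params,
                "package_version": __version__}
    write_sidecar(out_dir / "manifest", manifest)
    return summary
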