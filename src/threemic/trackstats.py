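"""Single-cell migration statistics on track ensembles.

Speeds, net displacement and path length, persistence (net/path), runner
classification at a displacement threshold, mean-squared-displacement (MSD)
curves with a power-law exponent fit and bootstrap confidence interval, and
directional-bias statistics (compass vectors, Rayleigh and Moore tests).

The MSD exponent is the slope of log MSD against log lag: 1 for a random
walk, 2 for straight-line motion, and between the two for persistent
(superdiffusive) migration. An ensemble is called superdiffusive when the
bootstrap CI for the exponent lies entirely above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Track, TrackSet
from .errors import FitError, InsufficientDataError, SpecError, TrackIntegrityError

#: tracks missing more than this fraction of frames are excluded from MSD pooling
MAX_MISSING_FRACTION = 0.10
#: tracks shorter than this many frames are excluded from exponent fitting
MIN_FRAMES_FOR_MSD = 6
#: direction of the chamber opening (toward nutrients) in image coordinates
OPENING_DIRECTION = np.array([-1.0, 0.0])


# ---------------------------------------------------------------------------
# per-track scalars
# ---------------------------------------------------------------------------


def instantaneous_speeds(track: Track) -> np.ndarray:
    """|Δposition|/Δt per consecutive frame pair, μm/min; length n-1."""
    dt = np.diff(track.t_min)
    if np.any(dt <= 0):
        raise TrackIntegrityError(f"track {track.track_id}: non-increasing time")
    disp = np.hypot(np.diff(track.x_um), np.diff(track.y_um))
    return disp / dt


def net_displacement(track: Track) -> float:
    """Straight-line distance between first and last position, μm."""
    return float(np.hypot(track.x_um[-1] - track.x_um[0],
                          track.y_um[-1] - track.y_um[0]))


def path_length(track: Track) -> float:
    """Total trajectory length, μm; always >= net displacement."""
    return float(np.sum(np.hypot(np.diff(track.x_um), np.diff(track.y_um))))


def persistence(track: Track) -> float:
    """Net displacement over path length; 1 = straight, 0 = closed loop.

    Returns NaN (flagged missing) for a track that never moved.
    """
    path = path_length(track)
    if path == 0:
        return float("nan")
    return net_displacement(track) / path


# ---------------------------------------------------------------------------
# runner classification
# ---------------------------------------------------------------------------


@dataclass
class RunnerConfig:
    """Net-displacement threshold defining a 'runner' (default 50 μm).

    The inclusive rule (net displacement >= threshold) is the default;
    ``strict`` switches to a strictly-greater comparison.
    """

    threshold_um: float = 50.0
    strict: bool = False

    def __post_init__(self) -> None:
        if self.threshold_um <= 0:
            raise SpecError("threshold_um must be positive")


@dataclass
class RunnerResult:
    flags: np.ndarray
    count: int
    fraction: float
    threshold_um: float


def classify_runners(trackset: TrackSet, config: RunnerConfig | None = None) -> RunnerResult:
    """Flag tracks whose net displacement reaches the runner threshold."""
    if len(trackset) == 0:
        raise InsufficientDataError("empty track set")
    config = config or RunnerConfig()
    nets = np.array([net_displacement(t) for t in trackset])
    flags = nets > config.threshold_um if config.strict else nets >= config.threshold_um
    return RunnerResult(flags, int(flags.sum()), float(flags.mean()),
                        config.threshold_um)


def runner_threshold_sweep(
    trackset: TrackSet, thresholds_um: np.ndarray
) -> np.ndarray:
    """Runner fraction at each threshold (for sensitivity analyses)."""
    nets = np.array([net_displacement(t) for t in trackset])
    return np.array([(nets >= th).mean() for th in np.asarray(thresholds_um)])


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------


@dataclass
class MSDCurve:
    """Mean squared displacement against lag time, with pair counts."""

    lag_min: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    scheme: str = "time_averaged_pooled"


def _eligible(trackset: TrackSet) -> list[Track]:
    return [
        t for t in trackset
        if t.n_samples >= 2 and t.missing_fraction() <= MAX_MISSING_FRACTION
    ]


def _per_track_sq_disp(track: Track, max_lag_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum of squared displacements and pair count per lag index (time average)."""
    xy = track.xy
    n = len(xy)
    k_max = min(max_lag_idx, n - 1)
    sums = np.zeros(k_max)
    counts = np.zeros(k_max, dtype=int)
    for k in range(1, k_max + 1):
        d = xy[k:] - xy[:-k]
        sums[k - 1] = np.sum(d[:, 0] ** 2 + d[:, 1] ** 2)
        counts[k - 1] = n - k
    return sums, counts


def _pooled_matrices(
    tracks: list[Track], max_lag_quarter: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-track (sum, count) matrices on a common lag grid.

    Lags run up to a quarter of the longest eligible track's frame count
    (time-averaged MSD estimates beyond that are dominated by noise);
    each track contributes up to a quarter of its own duration.
    """
    dt = float(np.median([t.nominal_dt_min() for t in tracks]))
    n_max = max(t.n_samples for t in tracks)
    k_pool = max(n_max // 4, 1) if max_lag_quarter else n_max - 1
    sums = np.zeros((len(tracks), k_pool))
    counts = np.zeros((len(tracks), k_pool), dtype=int)
    for i, t in enumerate(tracks):
        k_i = max(t.n_samples // 4, 1) if max_lag_quarter else t.n_samples - 1
        s, c = _per_track_sq_disp(t, min(k_i, k_pool))
        sums[i, : len(s)] = s
        counts[i, : len(c)] = c
    lags = dt * np.arange(1, k_pool + 1)
    return lags, sums, counts


def msd(trackset: TrackSet, scheme: str = "time_averaged_pooled") -> MSDCurve:
    """MSD curve for an ensemble of tracks.

    ``time_averaged_pooled`` averages squared displacements over all start
    times and all tracks at each lag (the default; stable at long lag).
    ``ensemble`` averages squared displacement from each track's origin at
    fixed lag index.
    """
    tracks = _eligible(trackset)
    if not tracks:
        raise InsufficientDataError("no eligible tracks for MSD")
    if scheme == "time_averaged_pooled":
        lags, sums, counts = _pooled_matrices(tracks)
        tot = counts.sum(axis=0)
        keep = tot > 0
        return MSDCurve(lags[keep], sums.sum(axis=0)[keep] / tot[keep],
                        tot[keep], scheme)
    if scheme == "ensemble":
        dt = float(np.median([t.nominal_dt_min() for t in tracks]))
        n_min = min(t.n_samples for t in tracks)
        xy0 = np.stack([t.xy[0] for t in tracks])
        vals, counts = [], []
        for k in range(1, n_min):
            d = np.stack([t.xy[k] for t in tracks]) - xy0
            vals.append(np.mean(d[:, 0] ** 2 + d[:, 1] ** 2))
            counts.append(len(tracks))
        return MSDCurve(dt * np.arange(1, n_min), np.array(vals),
                        np.array(counts), scheme)
    raise SpecError(f"unknown MSD scheme {scheme!r}")


# ---------------------------------------------------------------------------
# exponent fit
# ---------------------------------------------------------------------------


@dataclass
class MSDFit:
    """Power-law fit MSD(τ) = prefactor · τ^exponent over a lag window."""

    exponent: float
    prefactor: float
    fit_lags: np.ndarray
    r2: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    flags: dict = field(default_factory=dict)

    @property
    def superdiffusive(self) -> bool:
        """True when the bootstrap CI lies entirely above the random-walk slope 1."""
        return bool(self.ci_low > 1.0)


MIN_FIT_LAGS = 5
MIN_PAIRS_PER_LAG = 20


def _loglog_slope(lags, msd_vals) -> tuple[float, float, float]:
    x = np.log(lags)
    y = np.log(msd_vals)
    A = np.column_stack([x, np.ones_like(x)])
    (slope, logc), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (res[0] / ss_tot if res.size and ss_tot > 0 else 0.0)
    return float(slope), float(np.exp(logc)), float(r2)


def fit_msd_exponent(
    curve: MSDCurve,
    trackset: TrackSet | None = None,
    fit_fraction: float = 0.25,
    n_boot: int = 500,
    ci_level: float = 0.95,
    seed: int = 0,
) -> MSDFit:
    """Least-squares slope of log MSD vs log lag over the short-lag window.

    The fit uses the first ``fit_fraction`` of available lags (default the
    first quarter) with at least ``MIN_PAIRS_PER_LAG`` displacement pairs
    each. When the originating ``trackset`` is supplied, a bootstrap over
    tracks gives a percentile confidence interval for the exponent.
    """
    usable = curve.n_pairs >= MIN_PAIRS_PER_LAG
    lags = curve.lag_min[usable]
    vals = curve.msd_um2[usable]
    n_fit = max(int(np.ceil(len(lags) * fit_fraction)), MIN_FIT_LAGS)
    if len(lags) < MIN_FIT_LAGS:
        raise FitError(
            f"need >= {MIN_FIT_LAGS} lags with >= {MIN_PAIRS_PER_LAG} pairs; "
            f"have {len(lags)}"
        )
    lags, vals = lags[:n_fit], vals[:n_fit]
    if np.any(vals <= 0):
        raise FitError("MSD values must be positive for a log-log fit "
                       "(frozen dynamics?)")
    slope, pref, r2 = _loglog_slope(lags, vals)
    fit = MSDFit(slope, pref, lags, r2)
    if trackset is not None:
        tracks = [t for t in _eligible(trackset) if t.n_samples >= MIN_FRAMES_FOR_MSD]
        if len(tracks) < 2:
            raise FitError("bootstrap needs >= 2 eligible tracks")
        all_lags, sums, counts = _pooled_matrices(tracks)
        rng = np.random.default_rng(seed)
        n = len(tracks)
        slopes = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            tot = counts[idx].sum(axis=0)
            s = sums[idx].sum(axis=0)
            ok = tot >= MIN_PAIRS_PER_LAG
            bl = all_lags[ok][:n_fit]
            bv = (s[ok] / tot[ok])[:n_fit]
            good = bv > 0
            if good.sum() < 2:
                slopes[b] = np.nan
                continue
            slopes[b], _, _ = _loglog_slope(bl[good], bv[good])
        slopes = slopes[np.isfinite(slopes)]
        if len(slopes) < n_boot // 2:
            raise FitError("bootstrap failed on most resamples")
        alpha = (1.0 - ci_level) / 2
        fit.ci_low = float(np.quantile(slopes, alpha))
        fit.ci_high = float(np.quantile(slopes, 1 - alpha))
        fit.n_boot = len(slopes)
    return fit


# ---------------------------------------------------------------------------
# directionality
# ---------------------------------------------------------------------------


@dataclass
class DisplacementVectors:
    """Final-minus-initial displacement vectors, origin-centered."""

    vectors: np.ndarray      # (n, 2) in μm
    vector_sum: np.ndarray   # (2,)
    angles: np.ndarray       # radians; 0 = toward the chamber opening
    magnitudes: np.ndarray


def displacement_vectors(
    trackset: TrackSet, opening_direction: np.ndarray | None = None
) -> DisplacementVectors:
    """Compass-plot data: per-track displacement vectors and their sum.

    Angles are measured relative to the chamber-opening direction (toward
    nutrients; default -x in image coordinates), so a positive resultant at
    angle 0 means net movement toward the nutrient source.
    """
    if len(trackset) == 0:
        raise InsufficientDataError("empty track set")
    u = np.asarray(opening_direction if opening_direction is not None
                   else OPENING_DIRECTION, dtype=float)
    u = u / np.linalg.norm(u)
    v_perp = np.array([-u[1], u[0]])
    vecs = np.stack([
        [t.x_um[-1] - t.x_um[0], t.y_um[-1] - t.y_um[0]] for t in trackset
    ])
    angles = np.arctan2(vecs @ v_perp, vecs @ u)
    return DisplacementVectors(
        vectors=vecs,
        vector_sum=vecs.sum(axis=0),
        angles=angles,
        magnitudes=np.hypot(vecs[:, 0], vecs[:, 1]),
    )


@dataclass
class DirectionalTestResult:
    rayleigh_z: float
    rayleigh_p: float
    moore_r: float | None = None
    moore_p: float | None = None


def _rayleigh(angles: np.ndarray) -> tuple[float, float]:
    n = len(angles)
    rbar = np.hypot(np.cos(angles).sum(), np.sin(angles).sum()) / n
    z = n * rbar**2
    # small-sample corrected p (adequate for n < 50)
    p = np.exp(-z) * (
        1 + (2 * z - z**2) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
    )
    return float(z), float(min(max(p, 0.0), 1.0))


def _moore_r(angles: np.ndarray, ranks: np.ndarray) -> float:
    n = len(angles)
    return float(
        np.hypot((ranks * np.cos(angles)).sum(), (ranks * np.sin(angles)).sum())
        / n**1.5
    )


def directional_test(
    angles,
    weights=None,
    n_sim: int = 9999,
    seed: int = 0,
) -> DirectionalTestResult:
    """Rayleigh test for directional bias; Moore's variant with magnitudes.

    The Rayleigh test checks the null of uniform directions via Z = n·R̄²
    with a small-sample series correction of the p-value. When displacement
    magnitudes are supplied, Moore's rank-weighted statistic R* is also
    computed, with its p-value from a seeded Monte Carlo null (uniform
    angles, same ranks).
    """
    angles = np.asarray(angles, dtype=float)
    if len(angles) < 5:
        raise InsufficientDataError("need >= 5 angles for a directional test")
    z, p = _rayleigh(angles)
    result = DirectionalTestResult(z, p)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(angles):
            raise SpecError("weights must match angles in length")
        ranks = np.argsort(np.argsort(w)) + 1.0
        r_obs = _moore_r(angles, ranks)
        rng = np.random.default_rng(seed)
        n = len(angles)
        sims = rng.uniform(0, 2 * np.pi, size=(n_sim, n))
        rs = np.hypot(
            (ranks * np.cos(sims)).sum(axis=1), (ranks * np.sin(sims)).sum(axis=1)
        ) / n**1.5
        result.moore_r = r_obs
        result.moore_p = float((1 + np.sum(rs >= r_obs)) / (1 + n_sim))
    return result
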