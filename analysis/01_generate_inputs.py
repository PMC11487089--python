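"""Generate one example of every synthetic input class.

Writes a smooth and a ruffled spheroid mask, a nuclei point cloud, the two
track ensembles (brownian / persistent), a two-channel pH-ratio image, and
a drug-decay profile, each with its JSON sidecar, under results/01_inputs/.
These are the same generators the test suite and acceptance analyses use;
this script exists to make the raw inputs inspectable.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import tifffile

from threemic import synthgen
from threemic.core import GradientProfile
from threemic.io import write_labels, write_profile, write_sidecar, write_tracks
from threemic.pipeline import child_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/01_inputs"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    for name, amp in [("smooth", 0.0), ("ruffled", 0.35)]:
        spec = synthgen.ShapeSpec(radius_px=120, ruffle_amplitude=amp,
                                  ruffle_modes=(8,), seed=child_seed(args.seed, 1))
        write_labels(synthgen.make_spheroid_mask(spec), out / f"mask_{name}.tif", spec)

    pts = synthgen.make_nuclei_points(100, (200.0, 200.0), dispersion=4.0,
                                      seed=child_seed(args.seed, 2))
    np.savetxt(out / "nuclei_um.csv", pts.xy, delimiter=",", header="x_um,y_um")

    for model in ("brownian", "persistent"):
        spec = synthgen.WalkSpec(model=model, n_tracks=50, n_steps=96,
                                 dt_min=15.0, step_scale_um=2.0,
                                 persistence_time_min=90.0,
                                 seed=child_seed(args.seed, 3))
        write_tracks(synthgen.make_tracks(spec), out / f"tracks_{model}.csv", spec)

    d = np.linspace(0, 10, 21)
    ratio = GradientProfile(d, 1.2 + 0.08 * d, value_kind="ratio")
    img = synthgen.make_gradient_image(10.0, ratio, noise_sd=1.0,
                                       seed=child_seed(args.seed, 4))
    for ch, arr in img.channels.items():
        tifffile.imwrite(out / f"gradient_{ch}.tif", arr.astype(np.float32))
    write_sidecar(out / "gradient", img.meta)

    decay = synthgen.make_decay_profile(150.0, 8.3, 14.0)
    write_profile(decay, out / "drug_intensity.csv")

    print(f"wrote synthetic inputs to {out}")
    print(json.dumps({"files": sorted(p.name for p in out.iterdir())}, indent=2))


if __name__ == "__main__":
    main()
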