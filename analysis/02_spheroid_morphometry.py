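"""Spheroid shape along the chamber: invasiveness index vs distance.

Runs the invasiveness-gradient scenario: synthetic spheroids whose
boundary ruffling grows with distance from the opening are measured with
the shape index (perimeter over equal-area-circle perimeter), and the
index is fit linearly against distance. A positive fitted slope with high
Pearson r reproduces the hallmark morphological readout: distal (ischemic)
spheroids are more protrusive than proximal (well-nurtured) ones.
"""

import argparse
import json
from pathlib import Path

from threemic.pipeline import run_scenario


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/02_morphometry"))
    args = ap.parse_args()
    summary = run_scenario({"scenario": "invasiveness_gradient",
                            "seed": args.seed, "out_dir": str(args.out)})
    print(json.dumps(summary, indent=2, sort_keys=True))
    print(f"\nInvasiveness rises by {summary['slope_per_mm']:.3f} per mm of "
          f"distance from the opening (Pearson r = {summary['pearson_r']:.3f}); "
          f"smooth proximal spheroids sit near the circular minimum of 1.")


if __name__ == "__main__":
    main()
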