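#!/usr/bin/env python
"""Simulate the study cohort: 10 subjects x 9 activities x 3 placements.

Writes one CSV recording pair per bout plus a manifest.  The defaults
reproduce the study conditions (10-minute bouts, ~30% goofy stance); the
raw dataset is large, so it goes under scratch/ by default.
"""

import argparse
from pathlib import Path

import pushglide as pg


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--subjects", type=int, default=10)
    ap.add_argument("--duration", type=float, default=600.0)
    ap.add_argument("--goofy-fraction", type=float, default=0.3)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("scratch/dataset"))
    args = ap.parse_args()

    cohort = pg.make_cohort(args.subjects, args.goofy_fraction, args.seed)
    manifest = pg.synthesize_dataset(cohort, args.duration, args.seed, args.out)
    n_goofy = sum(p.stance.value == "goofy" for p in cohort)
    print(f"cohort: {len(cohort)} subjects ({n_goofy} goofy stance)")
    print(f"wrote {len(manifest)} recordings ({args.duration:g}-s bouts) to {args.out}")
    print(manifest.groupby(["activity", "placement"]).size().unstack())


if __name__ == "__main__":
    main()
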