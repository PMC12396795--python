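#!/usr/bin/env python
"""Window the simulated recordings and extract the 211-feature table.

Each bout is trimmed by 5 s at both ends, resampled to an exact 100 Hz
grid, cut into non-overlapping analytic windows, and reduced to the fixed
feature schema.  The per-window table (a few MB) goes under scratch/.
"""

import argparse
from pathlib import Path

import pandas as pd

import pushglide as pg
from pushglide import features as feat


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/dataset"))
    ap.add_argument("--window", type=int, choices=(10, 20), default=20)
    ap.add_argument("--trim", type=float, default=5.0)
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()
    out = args.out or Path(f"scratch/features_w{args.window}.csv")

    manifest = pd.read_csv(args.data / "manifest.csv")
    frames = []
    for _, row in manifest.iterrows():
        rec = pg.read_recording(args.data / row["file"])
        windows = pg.prepare_windows(rec, length_s=args.window, trim_s=args.trim)
        frames.append(feat.extract_table(windows))
    table = pd.concat(frames, ignore_index=True)
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, index=False, float_format="%.6g")
    print(f"extracted {len(table)} windows x {len(feat.FEATURE_SCHEMA)} features -> {out}")
    print(table.groupby(["activity", "placement"]).size().unstack())


if __name__ == "__main__":
    main()
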