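#!/usr/bin/env python
"""Render the headline accuracy grid from the evaluation tables.

Rows are (task, window), columns the four device configurations, cells
integer "mean (SD)" percents, matching the publication table style.
"""

import argparse
from pathlib import Path

import pandas as pd

from pushglide.reporting import format_cell


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    acc = pd.read_csv(args.results / "balanced_accuracy.csv")
    acc["cell"] = [
        format_cell(m, s)
        for m, s in zip(acc["balanced_accuracy_mean_pct"], acc["balanced_accuracy_sd_pct"])
    ]
    grid = acc.pivot_table(
        index=["task", "window_s"], columns="configuration", values="cell",
        aggfunc="first",
    )
    grid.to_csv(args.results / "accuracy_grid.csv")
    print(grid.to_string())
    print(f"\nwrote {args.results / 'accuracy_grid.csv'}")


if __name__ == "__main__":
    main()
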