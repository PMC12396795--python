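"""Publication-style tables from evaluation summaries.

The headline grid follows the study's table style: rows are
(task, window length), columns the four device configurations, each cell
an integer "mean (SD)" percent.  Full precision stays in the per-summary
CSVs; confusion tables are row-normalized sensitivities.
"""

from __future__ import annotations

import pandas as pd


def format_cell(mean_pct: float, sd_pct: float) -> str:
    """Render "mean (SD)" with integer percents, e.g. 87.45, 4.9 -> "87 (5)"."""
    return f"{round(mean_pct):d} ({round(sd_pct):d})"


def accuracy_grid(summaries) -> pd.DataFrame:
    """task x window rows, configuration columns, "mean (SD)" percent cells."""
    if not summaries:
        raise ValueError("no summaries to render")
    rows = {}
    for s in summaries:
        key = (s.task, f"{s.window_length:g}-s window")
        rows.setdefault(key, {})[s.configuration] = format_cell(
            s.balanced_accuracy_mean, s.balanced_accuracy_sd
        )
    grid = pd.DataFrame.from_dict(rows, orient="index")
    grid.index = pd.MultiIndex.from_tuples(grid.index, names=["task", "window"])
    return grid.sort_index()


def render_reports(summaries) -> dict[str, pd.DataFrame]:
    """All report tables: the accuracy grid plus per-summary confusion and
    top-10 importance tables, keyed by file-friendly names."""
    out: dict[str, pd.DataFrame] = {"accuracy_grid": accuracy_grid(summaries)}
    for s in summaries:
        stem = f"{s.task}_{s.configuration}_w{s.window_length:g}"
        out[f"confusion_{stem}"] = s.confusion
        out[f"importance_top10_{stem}"] = s.top_features(10).to_frame("gini_importance")
    return out
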