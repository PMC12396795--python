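"""End-to-end pipeline: simulate -> window -> extract -> evaluate -> report.

``PipelineConfig`` defaults mirror the study protocol: 10-minute bouts,
5-s boundary trims, 10/20-s non-overlapping windows, 100-tree forests,
100 runs per 8:2 subject split, every split.  ``run_pipeline`` executes
the stages into a work directory and emits a manifest with SHA-256 hashes
of every artifact, so identical configurations produce identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import features as feat
from . import io_windowing, synthetic_data
from .experiments import DEVICE_CONFIGURATIONS, TASKS, run_task
from .reporting import render_reports

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Structured configuration for one full pipeline run."""

    # simulate
    subjects: int = 10
    duration_s: float = 600.0
    goofy_fraction: float = 0.3
    seed: int = 0
    # segment / extract
    window_s: tuple[int, ...] = (10, 20)
    stride_s: float | None = None  # None -> non-overlapping
    trim_s: float = 5.0
    # evaluate
    tasks: tuple[str, ...] = TASKS
    configs: tuple[str, ...] = tuple(DEVICE_CONFIGURATIONS)
    runs: int = 100
    trees: int = 100
    max_splits: int | None = None
    # paths
    workdir: str = "pushglide_run"

    def validate(self) -> None:
        for w in self.window_s:
            if w not in io_windowing.WINDOW_LENGTHS_S:
                raise ValueError(
                    f"window_s must be drawn from {io_windowing.WINDOW_LENGTHS_S}; got {w}"
                )
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r}")
        for c in self.configs:
            if c not in DEVICE_CONFIGURATIONS:
                raise ValueError(f"unknown configuration {c!r}")
        if self.subjects < 2:
            raise ValueError("subjects must be >= 2")
        if self.duration_s < 40:
            raise ValueError("duration_s must be >= 40")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def build_feature_table(
    cohort,
    duration_s: float,
    seed: int,
    window_s: int = 20,
    stride_s: float | None = None,
    trim_s: float = 5.0,
) -> pd.DataFrame:
    """Simulate a cohort and extract the full 211-feature table in memory.

    Recordings are generated, trimmed, resampled, windowed and reduced to
    features one at a time, so peak memory stays at one bout.
    """
    frames = []
    for rec in synthetic_data.iter_recordings(cohort, duration_s, seed):
        windows = io_windowing.prepare_windows(
            rec, length_s=window_s, stride_s=stride_s, trim_s=trim_s
        )
        frames.append(feat.extract_table(windows))
    return pd.concat(frames, ignore_index=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline into ``config.workdir``.

    Returns a dict with the evaluation summaries and the artifact manifest
    (relative path -> SHA-256).  Stage failures raise with the stage name.
    """
    config.validate()
    work = Path(config.workdir)
    for sub in ("data", "features", "results", "reports"):
        (work / sub).mkdir(parents=True, exist_ok=True)
    config.to_yaml(work / "config.yaml")

    stage = "simulate"
    try:
        cohort = synthetic_data.make_cohort(
            config.subjects, config.goofy_fraction, config.seed
        )
        manifest = synthetic_data.synthesize_dataset(
            cohort, config.duration_s, config.seed, work / "data"
        )

        stage = "segment/extract"
        tables = []
        for w in config.window_s:
            tbl = build_feature_table(
                cohort,
                config.duration_s,
                config.seed,
                window_s=w,
                stride_s=config.stride_s,
                trim_s=config.trim_s,
            )
            tbl.to_csv(
                work / "features" / f"features_w{w}.csv",
                index=False,
                float_format="%.6g",
            )
            tables.append((w, tbl))

        stage = "evaluate"
        summaries = []
        for w, tbl in tables:
            for task in config.tasks:
                for cname in config.configs:
                    summaries.append(
                        run_task(
                            tbl,
                            task,
                            cname,
                            window_length=w,
                            n_runs=config.runs,
                            n_trees=config.trees,
                            seed=config.seed,
                            max_splits=config.max_splits,
                        )
                    )

        stage = "report"
        reports = render_reports(summaries)
        for name, df in reports.items():
            df.to_csv(work / "reports" / f"{name}.csv", float_format="%.6g")
        results = pd.DataFrame(
            [
                {
                    "task": s.task,
                    "configuration": s.configuration,
                    "window_s": s.window_length,
                    "balanced_accuracy_mean_pct": s.balanced_accuracy_mean,
                    "balanced_accuracy_sd_pct": s.balanced_accuracy_sd,
                    "n_splits": s.n_splits,
                    "n_runs": s.n_runs,
                    "n_trees": s.n_trees,
                }
                for s in summaries
            ]
        )
        results.to_csv(work / "results" / "balanced_accuracy.csv", index=False,
                       float_format="%.6g")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    artifact_manifest = {
        str(p.relative_to(work)): _sha256(p)
        for p in sorted(work.rglob("*.csv"))
    }
    pd.Series(artifact_manifest, name="sha256").rename_axis("file").to_csv(
        work / "artifact_manifest.csv"
    )
    logger.info("pipeline complete: %d summaries, %d artifacts",
                len(summaries), len(artifact_manifest))
    return {
        "summaries": summaries,
        "manifest": manifest,
        "artifacts": artifact_manifest,
    }
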