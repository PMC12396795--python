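"""Subject-wise random-forest evaluation across device configurations.

The protocol: for every 8:2 subject split (all C(n, 2) splits by default)
and each of ``n_runs`` forest seeds, fit a 100-tree random forest with
class-balanced sample weights on the training subjects' windows — the
feature columns masked to the device configuration's sensor set — and
predict the held-out subjects' windows.  Confusion counts are averaged
over runs within a split; the summary mean and SD of balanced accuracy
are taken across splits.  Gini (mean decrease in impurity) importances
are averaged over every fitted forest.

Five tasks are supported: the 9-class problem; kickboard-vs-rest and
skateboard-vs-rest (evaluated by extracting the corresponding one-vs-rest
estimator trained on the full activity list); push-push-glide-vs-rest
(kickboard + skateboard merged into one positive superclass, trained
fresh); and kickboard-vs-skateboard (those two activities only).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import features as feat
from .types import Activity

logger = logging.getLogger(__name__)

PPG_ACTIVITIES = (Activity.KICKBOARD.value, Activity.SKATEBOARD.value)


@dataclass(frozen=True)
class DeviceConfiguration:
    """A (placement, sensor subset) pair emulating a commercial tracker."""

    name: str
    placement: str
    sensor_set: tuple[str, ...]

    @property
    def feature_columns(self) -> list[str]:
        return feat.feature_names(self.sensor_set)


#: The four commercial-device archetypes.
DEVICE_CONFIGURATIONS = {
    "hip_accel": DeviceConfiguration("hip_accel", "hip", ("accel",)),
    "pocket_full": DeviceConfiguration("pocket_full", "pocket", ("accel", "gyro", "baro")),
    "wrist_accel": DeviceConfiguration("wrist_accel", "wrist", ("accel",)),
    "wrist_full": DeviceConfiguration("wrist_full", "wrist", ("accel", "gyro", "baro")),
}

TASKS = ("multiclass", "kick_vs_rest", "skate_vs_rest", "ppg_vs_rest", "kick_vs_skate")

#: Tasks evaluated by extracting a one-vs-rest estimator trained on all 9 classes.
_OVR_TASKS = {"kick_vs_rest": Activity.KICKBOARD.value,
              "skate_vs_rest": Activity.SKATEBOARD.value}


def task_labels(task: str, activities: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Map activity labels to task labels; returns (labels, row mask)."""
    if task == "multiclass":
        return activities, pd.Series(True, index=activities.index)
    if task in _OVR_TASKS:
        target = _OVR_TASKS[task]
        return (activities == target).map({True: target, False: "rest"}), pd.Series(
            True, index=activities.index
        )
    if task == "ppg_vs_rest":
        lab = activities.isin(PPG_ACTIVITIES).map({True: "ppg", False: "rest"})
        return lab, pd.Series(True, index=activities.index)
    if task == "kick_vs_skate":
        mask = activities.isin(PPG_ACTIVITIES)
        return activities, mask
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def enumerate_splits(subject_ids, test_size: int = 2) -> list[tuple[tuple, tuple]]:
    """All C(n, test_size) subject-wise (train, test) splits, lexicographic.

    With 10 subjects and test_size 2 this is the full set of 45 splits.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in split enumeration")
    if test_size <= 0:
        raise ValueError("test_size must be positive")
    if len(ids) <= test_size:
        raise ValueError("need more subjects than test_size")
    ids = sorted(ids)
    plan = []
    for test in itertools.combinations(ids, test_size):
        train = tuple(s for s in ids if s not in test)
        plan.append((train, test))
    return plan


def class_balanced_weights(labels) -> np.ndarray:
    """Per-sample weights 1/count(class); each class's weights sum to 1."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean of per-class recalls from a confusion matrix (rows = true class).

    Classes with an empty row are excluded with a logged warning.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (confusion < 0).any():
        raise ValueError("confusion matrix must be nonnegative")
    rowsum = confusion.sum(axis=1)
    present = rowsum > 0
    if not present.all():
        logger.warning("%d class(es) absent from test data excluded from balanced accuracy",
                       int((~present).sum()))
    if not present.any():
        raise ValueError("confusion matrix has no populated rows")
    recalls = np.diag(confusion)[present] / rowsum[present]
    return float(recalls.mean())


def row_normalize(confusion: pd.DataFrame) -> pd.DataFrame:
    """Normalized sensitivities: each populated row scaled to sum to 1."""
    rs = confusion.sum(axis=1)
    out = confusion.div(rs.replace(0, np.nan), axis=0)
    return out


@dataclass
class EvaluationSummary:
    """Per-(task, configuration, window length) evaluation results."""

    task: str
    configuration: str
    window_length: float
    balanced_accuracy_mean: float  # percent
    balanced_accuracy_sd: float  # percent, across splits
    per_split_accuracy: list[float]  # fractions, one per split
    confusion: pd.DataFrame  # row-normalized, pooled over splits
    importance: pd.Series  # mean Gini importance per feature
    n_splits: int
    n_runs: int
    n_trees: int
    split_audit: list[dict] = field(default_factory=list)

    def top_features(self, k: int = 10) -> pd.Series:
        return self.importance.sort_values(ascending=False).head(k)


def _prepare_matrix(table: pd.DataFrame, config: DeviceConfiguration,
                    window_length) -> tuple[pd.DataFrame, np.ndarray]:
    df = table[table["placement"] == config.placement]
    if window_length is not None:
        df = df[df["length_s"] == float(window_length)]
    if df.empty:
        raise ValueError(
            f"no windows for placement {config.placement!r} "
            f"and window length {window_length!r}"
        )
    cols = config.feature_columns
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing[:5]}...")
    X = df[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        n_bad = int(np.isnan(X).sum())
        logger.warning("imputing %d missing feature values as 0 for model fit", n_bad)
        X = np.nan_to_num(X, nan=0.0)
    return df.reset_index(drop=True), X


def run_task(
    feature_table: pd.DataFrame,
    task: str,
    config: DeviceConfiguration | str,
    window_length: float | None = None,
    n_runs: int = 100,
    n_trees: int = 100,
    seed: int = 0,
    max_splits: int | None = None,
    test_size: int | None = None,
) -> EvaluationSummary:
    """Run one (task, configuration) evaluation over subject-wise splits.

    ``max_splits`` caps the number of splits for desk-scale runs (a
    deterministic subsample drawn from ``seed``); the default runs every
    split with ``n_runs`` forests each, i.e. the full 45 x 100 protocol
    for a 10-subject cohort.
    """
    if isinstance(config, str):
        config = DEVICE_CONFIGURATIONS[config]
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    df, X = _prepare_matrix(feature_table, config, window_length)
    activities = df["activity"]
    labels, row_mask = task_labels(task, activities)

    subjects = sorted(df["subject_id"].unique())
    if test_size is None:
        # the 8:2 protocol holds out 2 subjects; degrade to 1 for tiny cohorts
        test_size = min(2, len(subjects) - 1)
    plan = enumerate_splits(subjects, test_size=test_size)
    master = np.random.SeedSequence([int(seed), 0x5EED])
    if max_splits is not None and max_splits < len(plan):
        pick_rng = np.random.default_rng(master.spawn(1)[0])
        idx = sorted(pick_rng.choice(len(plan), size=max_splits, replace=False).tolist())
        plan = [plan[i] for i in idx]

    classes = sorted(labels[row_mask].unique())
    for c in classes:
        if labels.eq(c).sum() == 0:  # pragma: no cover - defensive
            raise ValueError(f"task label {c!r} absent from the feature table")

    subj_arr = df["subject_id"].to_numpy()
    per_split_ba: list[float] = []
    pooled_conf = np.zeros((len(classes), len(classes)))
    importances = np.zeros(X.shape[1])
    n_fits = 0
    audit = []
    class_index = {c: i for i, c in enumerate(classes)}

    is_ovr = task in _OVR_TASKS
    mc_labels = activities.to_numpy()  # multiclass labels for OvR weighting

    for split_i, (train_subj, test_subj) in enumerate(plan):
        tr = np.isin(subj_arr, train_subj) & row_mask.to_numpy()
        te = np.isin(subj_arr, test_subj) & row_mask.to_numpy()
        assert not np.any(tr & te), "train/test subject overlap"
        y_tr = labels.to_numpy()[tr]
        present = set(np.unique(y_tr))
        missing_lab = [c for c in classes if c not in present]
        if missing_lab:
            raise ValueError(
                f"task label(s) {missing_lab} absent from training subjects {train_subj}"
            )
        # one-vs-rest tasks keep the weights of the full multiclass problem
        w_tr = class_balanced_weights(mc_labels[tr] if is_ovr else y_tr)
        split_conf = np.zeros_like(pooled_conf)
        for run_i in range(n_runs):
            rf_seed = int(
                np.random.default_rng(
                    np.random.SeedSequence([int(seed), split_i, run_i])
                ).integers(0, 2**31 - 1)
            )
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=rf_seed, n_jobs=1
            )
            clf.fit(X[tr], y_tr, sample_weight=w_tr)
            if is_ovr:
                target = _OVR_TASKS[task]
                pos = list(clf.classes_).index(target)
                proba = clf.predict_proba(X[te])[:, pos]
                pred = np.where(proba >= 0.5, target, "rest")
            else:
                pred = clf.predict(X[te])
            y_te = labels.to_numpy()[te]
            for yt, yp in zip(y_te, pred):
                split_conf[class_index[yt], class_index[yp]] += 1
            importances += clf.feature_importances_
            n_fits += 1
        per_split_ba.append(balanced_accuracy(split_conf))
        pooled_conf += split_conf
        audit.append({"train": train_subj, "test": test_subj})
        logger.info(
            "task=%s config=%s split=%d/%d ba=%.4f",
            task, config.name, split_i + 1, len(plan), per_split_ba[-1],
        )

    conf_df = pd.DataFrame(pooled_conf, index=classes, columns=classes)
    ba = np.asarray(per_split_ba)
    return EvaluationSummary(
        task=task,
        configuration=config.name,
        window_length=float(window_length) if window_length is not None else float("nan"),
        balanced_accuracy_mean=100.0 * float(ba.mean()),
        balanced_accuracy_sd=100.0 * float(ba.std(ddof=1)) if ba.size > 1 else 0.0,
        per_split_accuracy=per_split_ba,
        confusion=row_normalize(conf_df),
        importance=pd.Series(importances / max(n_fits, 1), index=config.feature_columns),
        n_splits=len(plan),
        n_runs=n_runs,
        n_trees=n_trees,
        split_audit=audit,
    )


def aggregate_importance(importance_series: list[pd.Series], top_k: int | None = None) -> pd.Series:
    """Mean Gini importance over fitted runs; optionally the top-k report."""
    if not importance_series:
        raise ValueError("no importances to aggregate")
    agg = pd.concat(importance_series, axis=1).mean(axis=1)
    agg = agg.sort_values(ascending=False)
    return agg.head(top_k) if top_k else agg
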