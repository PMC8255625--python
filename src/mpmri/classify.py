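"""Random-forest prediction tasks on VOI feature vectors.

Three tasks mirror the reference analysis: predict the structure a
feature vector belongs to (18 classes after excluding the smallest
structures), predict its functional group (5 classes), and discriminate
structures within one functional group. Each task is evaluated with
cross-validation (leave-one-out by default; stratified 5-fold
selectable) using 100-tree random forests, the whole procedure repeated
over re-seeded runs and averaged. Confusion counts are summed over
folds and runs and then row-normalized; feature importances are mean
impurity-decrease importances of forests refit on the full data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .reference import CONTRASTS, DEFAULT_EXCLUDED
from .features import FEATURE_NAMES, FEATURE_STATS

__all__ = [
    "FeatureTable",
    "TaskReport",
    "build_dataset",
    "run_task",
    "contrast_ablation",
    "normalize_confusion",
]

TASKS = ("all_structures", "functional_groups", "within_group")


class DatasetError(ValueError):
    """The feature table cannot support the requested task."""


@dataclass
class FeatureTable:
    """Design matrix plus metadata for one prediction task."""

    X: np.ndarray                 # (n_samples, n_features)
    y: np.ndarray                 # target labels (strings)
    feature_names: list[str]
    sample_ids: list[tuple[str, str]]
    task: str
    contrasts_active: tuple[str, ...] = CONTRASTS
    excluded_structures: frozenset[str] = field(default_factory=lambda: DEFAULT_EXCLUDED)


def _contrast_columns(contrasts: tuple[str, ...]) -> list[str]:
    return [f"{stat}_{c}" for c in contrasts for stat in FEATURE_STATS]


def build_dataset(
    table: pd.DataFrame,
    task: str,
    group: str | None = None,
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED,
    contrasts: tuple[str, ...] = CONTRASTS,
) -> FeatureTable:
    """Assemble the design matrix and targets for one prediction task.

    Parameters
    ----------
    table : DataFrame
        Output of :func:`mpmri.features.feature_table` (one row per
        (subject, structure) with 32 feature columns).
    task : str
        ``"all_structures"`` (targets are structure names),
        ``"functional_groups"`` (targets are group names) or
        ``"within_group"`` (structure names restricted to ``group``).
    """
    if task not in TASKS:
        raise DatasetError(f"unknown task {task!r}")
    missing_cols = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing_cols:
        raise DatasetError(f"feature columns missing: {missing_cols[:4]}...")

    df = table[~table["structure"].isin(excluded)]
    if task == "within_group":
        if group is None:
            raise DatasetError("within_group task requires a group name")
        df = df[df["group"] == group]
        if df.empty:
            raise DatasetError(f"no samples in group {group!r}")

    # Every subject must contribute every retained structure.
    pivot = df.groupby(["structure", "subject"]).size()
    per_structure = pivot.groupby("structure").size()
    n_subjects = df["subject"].nunique()
    incomplete = per_structure[per_structure != n_subjects]
    if len(incomplete):
        raise DatasetError(
            f"missing (subject, structure) rows for: {list(incomplete.index)}"
        )

    cols = _contrast_columns(contrasts)
    df = df.sort_values(["subject", "structure"], kind="stable")
    y = (df["group"] if task == "functional_groups" else df["structure"]).to_numpy()
    return FeatureTable(
        X=np.ascontiguousarray(df[cols].to_numpy(dtype=np.float64)),
        y=y,
        feature_names=cols,
        sample_ids=list(zip(df["subject"], df["structure"])),
        task=task if group is None else f"{task}({group})",
        contrasts_active=tuple(contrasts),
        excluded_structures=frozenset(excluded),
    )


@dataclass
class TaskReport:
    """Averaged results of one prediction task."""

    task: str
    classes: list[str]
    mean_accuracy: float
    per_run_accuracy: np.ndarray
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray          # row-normalized, rows = true class
    confusion_counts: np.ndarray   # summed over folds and runs
    importances: dict[str, float]
    contrast_importance: dict[str, float]
    n_runs: int
    cv: str
    seed: int


def normalize_confusion(counts: np.ndarray) -> np.ndarray:
    """Row-normalize a nonnegative confusion-count matrix.

    Nonzero rows are divided by their sum; all-zero rows stay zero.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("confusion counts must be nonnegative")
    sums = counts.sum(axis=1, keepdims=True)
    out = np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)
    return out


def _folds(y: np.ndarray, cv: str, rng_seed: int):
    n = len(y)
    if cv == "loo":
        for i in range(n):
            test = np.array([i])
            train = np.delete(np.arange(n), i)
            yield train, test
    elif cv == "kfold5":
        _, counts = np.unique(y, return_counts=True)
        n_splits = min(5, int(counts.min()))
        if n_splits < 5:
            warnings.warn(
                f"smallest class has {counts.min()} samples; "
                f"using {n_splits}-fold CV", stacklevel=3,
            )
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rng_seed)
        yield from skf.split(np.zeros(n), y)
    else:
        raise ValueError(f"unknown cv protocol {cv!r}")


def run_task(
    table: FeatureTable,
    n_runs: int = 100,
    cv: str = "loo",
    seed: int = 0,
    n_trees: int = 100,
) -> TaskReport:
    """Cross-validated random-forest evaluation averaged over runs.

    For run ``r`` (forest and fold-shuffle seed ``seed + r``) a fresh
    100-tree forest is fit on every training fold; per-run accuracies
    and confusion counts accumulate across runs. The report is
    bit-for-bit reproducible given the master seed.
    """
    X, y = table.X, table.y
    classes = sorted(set(y))
    if len(classes) < 2:
        raise DatasetError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    singletons = [c for c, n in counts.items() if n < 2]
    if singletons:
        warnings.warn(
            f"classes with a single sample under {cv}: {singletons}", stacklevel=2
        )
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[c] for c in y])

    k = len(classes)
    conf = np.zeros((k, k), dtype=np.int64)
    run_acc = np.empty(n_runs)
    importances_sum = np.zeros(X.shape[1])

    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for r in range(n_runs):
            run_seed = (seed + r) % (2**31)
            correct = 0
            for train, test in _folds(y, cv, run_seed):
                clf = RandomForestClassifier(
                    n_estimators=n_trees, random_state=run_seed
                )
                clf.fit(X[train], y_idx[train])
                pred = clf.predict(X[test])
                for t, p in zip(y_idx[test], pred):
                    conf[t, int(p)] += 1
                correct += int((pred == y_idx[test]).sum())
            run_acc[r] = correct / len(y)
            full = RandomForestClassifier(
                n_estimators=n_trees, random_state=run_seed
            )
            full.fit(X, y_idx)
            importances_sum += full.feature_importances_

    norm_conf = normalize_confusion(conf)
    per_class = {
        c: float(norm_conf[class_index[c], class_index[c]]) for c in classes
    }
    imp = importances_sum / importances_sum.sum()
    importances = dict(zip(table.feature_names, imp))
    contrast_importance = {
        c: float(sum(v for n, v in importances.items() if n.endswith(f"_{c}")))
        for c in table.contrasts_active
        if any(n.endswith(f"_{c}") for n in importances)
    }
    return TaskReport(
        task=table.task,
        classes=classes,
        mean_accuracy=float(run_acc.mean()),
        per_run_accuracy=run_acc,
        per_class_accuracy=per_class,
        confusion=norm_conf,
        confusion_counts=conf,
        importances=importances,
        contrast_importance=contrast_importance,
        n_runs=n_runs,
        cv=cv,
        seed=seed,
    )


def all_contrast_subsets() -> list[tuple[str, ...]]:
    """Singletons, pairs, triples, then all four contrasts, in order."""
    subsets: list[tuple[str, ...]] = []
    for size in (1, 2, 3, 4):
        subsets.extend(combinations(CONTRASTS, size))
    return subsets


def contrast_ablation(
    table: pd.DataFrame,
    task: str = "all_structures",
    subsets: list[tuple[str, ...]] | None = None,
    n_runs: int = 100,
    cv: str = "kfold5",
    seed: int = 0,
    group: str | None = None,
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED,
) -> dict[tuple[str, ...], float]:
    """Mean task accuracy per contrast subset (identical seeds per subset).

    Each subset restricts the design matrix to that contrast's 8
    features; results are keyed by subset and reported in monotone
    order (singletons, pairs, triples, all).
    """
    if subsets is None:
        subsets = all_contrast_subsets()
    if any(len(s) == 0 for s in subsets):
        raise ValueError("empty contrast subset")
    ordered = sorted(subsets, key=lambda s: (len(s), [CONTRASTS.index(c) for c in s]))
    out: dict[tuple[str, ...], float] = {}
    for subset in ordered:
        ft = build_dataset(
            table, task, group=group, excluded=excluded, contrasts=tuple(subset)
        )
        report = run_task(ft, n_runs=n_runs, cv=cv, seed=seed)
        out[tuple(subset)] = report.mean_accuracy
    return out
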