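"""First-order feature extraction from flattened VOI signals.

Each VOI's voxel data is flattened to a 1-D signal per contrast (in
canonical lexicographic voxel order) and summarized by eight features:
mean, variance, minimum and maximum of the signal, and the same four
statistics of its gradient -- 32 features per sample across the four
contrasts. Variance uses the population denominator (n); the gradient
uses central differences at interior points and one-sided differences
at the endpoints, with a forward-difference alternative available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SubjectVolumes
from .reference import CONTRASTS, NucleusSpec, load_reference_params
from .voi import VoxelBlock, subject_blocks

__all__ = [
    "FEATURE_STATS",
    "FEATURE_NAMES",
    "FeatureVector",
    "flatten_voi",
    "signal_features",
    "feature_vector",
    "feature_table",
]

#: The eight per-contrast statistics, in canonical order.
FEATURE_STATS: tuple[str, ...] = (
    "mean", "var", "min", "max",
    "mean_grad", "var_grad", "min_grad", "max_grad",
)

#: Canonical names of all 32 features (contrast-major order).
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{contrast}" for contrast in CONTRASTS for stat in FEATURE_STATS
)


@dataclass(frozen=True)
class FeatureVector:
    """The 32 named features of one (subject, structure) sample."""

    sample_id: tuple[str, str]
    features: dict[str, float]
    label_structure: str
    label_group: str

    def __post_init__(self) -> None:
        if tuple(self.features) != FEATURE_NAMES:
            raise ValueError("features must carry the 32 canonical names in order")
        vals = np.array(list(self.features.values()))
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite feature value")

    def as_array(self) -> np.ndarray:
        return np.array([self.features[n] for n in FEATURE_NAMES])


def flatten_voi(block: VoxelBlock, contrast: str) -> np.ndarray:
    """The block's 1-D signal for one contrast (canonical voxel order)."""
    if contrast not in block.values:
        raise KeyError(f"unknown contrast {contrast!r}")
    return np.asarray(block.values[contrast], dtype=float)


def signal_features(signal: np.ndarray, gradient: str = "central") -> dict[str, float]:
    """Eight first-order statistics of a 1-D signal and its gradient.

    ``gradient="central"`` uses :func:`numpy.gradient` (central
    differences, one-sided at the two endpoints, unit spacing);
    ``"forward"`` uses first differences. A length-1 signal has no
    gradient; its gradient features are defined as 0 with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or len(signal) == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    if len(signal) == 1:
        warnings.warn("length-1 signal: gradient features set to 0", stacklevel=2)
        grad = np.zeros(1)
    elif gradient == "central":
        grad = np.gradient(signal)
    elif gradient == "forward":
        grad = np.diff(signal)
    else:
        raise ValueError(f"unknown gradient convention {gradient!r}")
    return {
        "mean": float(signal.mean()),
        "var": float(signal.var()),
        "min": float(signal.min()),
        "max": float(signal.max()),
        "mean_grad": float(grad.mean()),
        "var_grad": float(grad.var()),
        "min_grad": float(grad.min()),
        "max_grad": float(grad.max()),
    }


def feature_vector(
    block: VoxelBlock,
    group_of: dict[str, str] | None = None,
    gradient: str = "central",
) -> FeatureVector:
    """All 32 features of one block, with structure and group labels."""
    if group_of is None:
        group_of = {s.name: s.group for s in load_reference_params()}
    feats: dict[str, float] = {}
    for contrast in CONTRASTS:
        stats = signal_features(flatten_voi(block, contrast), gradient=gradient)
        for stat in FEATURE_STATS:
            feats[f"{stat}_{contrast}"] = stats[stat]
    return FeatureVector(
        sample_id=(block.subject_id, block.structure),
        features=feats,
        label_structure=block.structure,
        label_group=group_of[block.structure],
    )


def feature_table(
    cohort: list[SubjectVolumes],
    specs: list[NucleusSpec] | None = None,
    gradient: str = "central",
) -> pd.DataFrame:
    """One row per (subject, structure): labels plus 32 feature columns."""
    if specs is None:
        specs = load_reference_params()
    group_of = {s.name: s.group for s in specs}
    rows = []
    for subject in cohort:
        for block in subject_blocks(subject, [s.name for s in specs]):
            fv = feature_vector(block, group_of, gradient=gradient)
            rows.append(
                {"subject": fv.sample_id[0], "structure": fv.label_structure,
                 "group": fv.label_group, **fv.features}
            )
    return pd.DataFrame(rows, columns=["subject", "structure", "group", *FEATURE_NAMES])
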