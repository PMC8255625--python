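"""VOI-level descriptive statistics.

Extracts per-(subject, structure) voxel blocks from co-registered maps
and reproduces the descriptive analysis: per-structure mean +/- SD,
ascending rankings, grand means over nuclei vs fiber tracts, and pooled
voxel-wise Pearson correlations between contrast pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import SubjectVolumes
from .reference import CONTRASTS, NucleusSpec, structure_labels, structure_names

__all__ = [
    "VoxelBlock",
    "StructureSummary",
    "CorrelationResult",
    "extract_voi",
    "subject_blocks",
    "cohort_blocks",
    "summarize",
    "pool_and_summarize",
    "rank_structures",
    "grand_means",
    "summaries_from_specs",
    "pooled_correlation",
]


@dataclass
class VoxelBlock:
    """Index-aligned per-contrast voxel vectors of one (subject, VOI).

    Vectors follow canonical voxel order: lexicographic by (slice, row,
    column) ascending, i.e. C-order flat index.
    """

    subject_id: str
    structure: str
    values: dict[str, np.ndarray]
    voxel_order: str = "lex"

    def __post_init__(self) -> None:
        lengths = {c: len(v) for c, v in self.values.items()}
        if set(self.values) != set(CONTRASTS):
            raise ValueError(f"expected contrasts {CONTRASTS}, got {lengths}")
        n = len(next(iter(self.values.values())))
        if n < 1 or any(len(v) != n for v in self.values.values()):
            raise ValueError(f"contrast vectors unequal or empty: {lengths}")
        for c, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite entries in {c} vector")

    @property
    def n_voxels(self) -> int:
        return len(self.values[CONTRASTS[0]])

    def as_matrix(self) -> np.ndarray:
        """(n_voxels, 4) matrix in canonical contrast order."""
        return np.column_stack([self.values[c] for c in CONTRASTS])


@dataclass
class StructureSummary:
    """Per-contrast mean and SD of one VOI or pooled structure."""

    structure: str
    mean: dict[str, float]
    sd: dict[str, float]
    n_voxels: int
    scope: str = "single_subject"  # or "pooled"


@dataclass
class CorrelationResult:
    """Pearson correlation of one contrast pair over pooled VOI voxels."""

    contrast_pair: tuple[str, str]
    r: float
    p: float
    n: int


def extract_voi(
    maps: dict[str, np.ndarray],
    labels: np.ndarray,
    structure: str,
    label_map: dict[str, int] | None = None,
    subject_id: str = "",
) -> VoxelBlock:
    """Pull the voxel vectors of one labeled structure from four maps.

    Voxels appear in canonical lexicographic (slice, row, column) order.
    """
    if label_map is None:
        label_map = structure_labels()
    if structure not in label_map:
        raise KeyError(f"unknown structure {structure!r}")
    for c, vol in maps.items():
        if vol.shape != labels.shape:
            raise ValueError(
                f"map {c!r} shape {vol.shape} != labels shape {labels.shape}"
            )
    sel = labels == label_map[structure]
    if not sel.any():
        raise KeyError(f"label for {structure!r} absent from volume")
    # Boolean indexing of C-ordered arrays yields lexicographic order.
    return VoxelBlock(
        subject_id=subject_id,
        structure=structure,
        values={c: maps[c][sel].astype(float) for c in CONTRASTS},
    )


def subject_blocks(
    subject: SubjectVolumes, structures: list[str] | None = None
) -> list[VoxelBlock]:
    """Extract every structure's block from one synthetic subject."""
    if structures is None:
        structures = structure_names()
    lm = structure_labels()
    return [
        extract_voi(subject.maps, subject.labels, s, lm, subject.subject_id)
        for s in structures
    ]


def cohort_blocks(
    cohort: list[SubjectVolumes], structures: list[str] | None = None
) -> list[VoxelBlock]:
    """All (subject, structure) blocks of a cohort."""
    out: list[VoxelBlock] = []
    for subj in cohort:
        out.extend(subject_blocks(subj, structures))
    return out


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    if len(x) == 1:
        warnings.warn("single-voxel block: SD reported as 0", stacklevel=3)
        return float(x[0]), 0.0
    return float(x.mean()), float(x.std(ddof=1))


def summarize(block: VoxelBlock) -> StructureSummary:
    """Arithmetic mean and sample SD (n-1) per contrast of one block."""
    mean, sd = {}, {}
    for c in CONTRASTS:
        mean[c], sd[c] = _mean_sd(block.values[c])
    return StructureSummary(
        structure=block.structure, mean=mean, sd=sd,
        n_voxels=block.n_voxels, scope="single_subject",
    )


def pool_and_summarize(blocks: list[VoxelBlock]) -> StructureSummary:
    """Summary over the voxels of several subjects' blocks pooled."""
    if not blocks:
        raise ValueError("no blocks to pool")
    names = {b.structure for b in blocks}
    if len(names) != 1:
        raise ValueError(f"blocks span multiple structures: {sorted(names)}")
    mean, sd = {}, {}
    for c in CONTRASTS:
        x = np.concatenate([b.values[c] for b in blocks])
        mean[c], sd[c] = _mean_sd(x)
    n = sum(b.n_voxels for b in blocks)
    return StructureSummary(
        structure=blocks[0].structure, mean=mean, sd=sd,
        n_voxels=n, scope="pooled",
    )


def rank_structures(
    summaries: list[StructureSummary], contrast: str
) -> list[StructureSummary]:
    """Ascending ranking by mean value; ties break alphabetically."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries to rank")
    if contrast not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast!r}")
    return sorted(summaries, key=lambda s: (s.mean[contrast], s.structure))


def summaries_from_specs(specs: list[NucleusSpec]) -> list[StructureSummary]:
    """Turn the reference parameter table into pooled-style summaries."""
    return [
        StructureSummary(
            structure=s.name,
            mean={c: s.mean_of(c) for c in CONTRASTS},
            sd={c: s.sd_of(c) for c in CONTRASTS},
            n_voxels=1,
            scope="pooled",
        )
        for s in specs
    ]


def grand_means(
    summaries: list[StructureSummary],
    subset: str = "nuclei",
    specs: list[NucleusSpec] | None = None,
) -> dict[str, tuple[float, float]]:
    """Unweighted mean and SD of per-structure means across a subset.

    ``subset`` selects the 19 nuclei or the 2 fiber tracts. The SD is
    the population SD (denominator n) across the structure means --
    structures, not voxels, are the units of this descriptive summary.
    """
    if subset not in ("nuclei", "fiber_tracts"):
        raise ValueError(f"subset must be 'nuclei' or 'fiber_tracts', got {subset!r}")
    if specs is None:
        from .reference import load_reference_params
        specs = load_reference_params()
    groups = {s.name: s.group for s in specs}
    want_fiber = subset == "fiber_tracts"
    wanted = [n for n, g in groups.items() if (g == "fiber_tract") == want_fiber]
    have = {s.structure: s for s in summaries}
    missing = [n for n in wanted if n not in have]
    if missing:
        raise ValueError(f"summaries missing for structures: {missing}")
    out: dict[str, tuple[float, float]] = {}
    for c in CONTRASTS:
        vals = np.array([have[n].mean[c] for n in wanted])
        out[c] = (float(vals.mean()), float(vals.std(ddof=0)))
    return out


def pooled_correlation(
    blocks: list[VoxelBlock], pair: tuple[str, str]
) -> CorrelationResult:
    """Pearson correlation of two contrasts over all VOI voxels pooled.

    Pools voxels across structures and subjects; two-sided p-value from
    the exact t transform with n - 2 degrees of freedom.
    """
    a, b = pair
    for c in (a, b):
        if c not in CONTRASTS:
            raise KeyError(f"unknown contrast {c!r}")
    x = np.concatenate([blk.values[a] for blk in blocks])
    y = np.concatenate([blk.values[b] for blk in blocks])
    if len(x) < 3:
        raise ValueError("need at least 3 pooled voxels")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a contrast: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        contrast_pair=(a, b), r=float(res.statistic),
        p=float(res.pvalue), n=len(x),
    )
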