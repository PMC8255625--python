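"""Synthetic multiparametric cohort generator.

Emulates the study design that produced the reference table: five
volunteers, 21 manually segmented subcortical VOIs, and four
co-registered quantitative maps per subject. Each (structure, contrast)
population is modeled as Gaussian with the tabulated mean and SD, split
hierarchically into a between-subject component (fraction ``f`` of the
total SD) and a within-VOI voxel component (the remaining
``sqrt(1 - f^2)``), so that the pooled SD converges to the tabulated
value by the law of total variance. A single 4x4 residual correlation
matrix ``R`` couples the contrasts identically at both levels, which
makes the total within-structure cross-contrast covariance
``sigma_c * sigma_d * R_cd`` independent of ``f``.

Structures are laid out as disjoint axis-aligned slabs on a regular
grid; no anatomical geometry is modeled because every downstream
analysis consumes voxel values only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .reference import (
    CONTRASTS,
    CSF_LABEL,
    CSF_SODIUM,
    NucleusSpec,
    load_reference_params,
    structure_names,
)

__all__ = [
    "CohortConfig",
    "SubjectVolumes",
    "CalibrationResult",
    "DEFAULT_VOXEL_COUNTS",
    "PAPER_CORRELATIONS",
    "sample_subject",
    "generate_cohort",
    "generate_raw_mt_pair",
    "generate_raw_sodium",
    "calibrate_residual_correlation",
    "predicted_pooled_correlation",
]

#: Default VOI sizes (voxels) per structure, proportional to typical
#: anatomical volumes of these structures (large striatal nuclei down to
#: millimetre-scale brainstem nuclei), sampled at roughly 2 mm isotropic
#: and floored at 10 voxels. Realistic, unequal VOI sizes matter: the
#: pooled voxel-wise cross-contrast correlations weight structures by
#: voxel count, and equal-size VOIs cannot reproduce the reference
#: correlation structure (see docs/methods.md).
DEFAULT_VOXEL_COUNTS: dict[str, int] = {
    "NC": 438, "RN": 38, "Pal": 188, "Put": 500, "NAC": 75, "LC": 10,
    "BNST": 19, "SN": 50, "STN": 15, "VTA": 12, "CP": 100, "DRN": 10,
    "LGB": 15, "MB": 12, "MGB": 12, "PPN": 12, "Pul": 125, "VP": 25,
    "HB": 10, "ML": 25, "NBM": 38,
}

#: Published pooled voxel-wise Pearson correlations between contrast
#: pairs (the sodium-QSM pair was not reported and is left free).
PAPER_CORRELATIONS: dict[tuple[str, str], float] = {
    ("t1", "na"): 0.58,
    ("t1", "mtr"): -0.46,
    ("na", "mtr"): -0.25,
    ("t1", "qsm"): -0.24,
    ("mtr", "qsm"): -0.01,
}

#: Synthetic CSF compartment: sodium at the physiological reference
#: concentration; the other contrasts carry plausible fluid values but
#: are never analysed (the CSF label exists for sodium referencing).
_CSF_MEAN = {"qsm": 0.0, "na": CSF_SODIUM, "mtr": 2.0, "t1": 4300.0}
_CSF_SD = {"qsm": 0.005, "na": 5.0, "mtr": 1.0, "t1": 100.0}


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


class GridSizeError(CohortConfigError):
    """Requested grid cannot hold all structures disjointly."""


def _as_correlation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (4, 4):
        raise CohortConfigError("residual correlation must be 4x4")
    if not np.allclose(R, R.T, atol=1e-12):
        raise CohortConfigError("residual correlation must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise CohortConfigError("residual correlation must have unit diagonal")
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise CohortConfigError("residual correlation must be positive semidefinite")
    return R


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Attributes
    ----------
    n_subjects : int
        Number of subjects (default 5, matching the reference study).
    voxels_per_structure : int or mapping
        VOI size per structure. An int applies to every structure; the
        default is the anatomically proportional table
        :data:`DEFAULT_VOXEL_COUNTS`.
    inter_subject_fraction : float
        Fraction ``f`` in [0, 1) of the total SD attributed to
        between-subject variation of the VOI mean.
    residual_correlation : ndarray (4, 4)
        Unit-diagonal PSD correlation applied to the subject-level and
        voxel-level Gaussian draws (contrast order qsm, na, mtr, t1).
    seed : int
        Master seed; all randomness derives from it deterministically.
    grid_shape : tuple of 3 ints, optional
        Volume shape (slices, rows, cols). ``None`` sizes the grid
        automatically from the voxel counts.
    csf_voxels : int
        Size of the CSF compartment.
    """

    n_subjects: int = 5
    voxels_per_structure: int | dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VOXEL_COUNTS)
    )
    inter_subject_fraction: float = 0.4
    residual_correlation: np.ndarray = field(default_factory=lambda: np.eye(4))
    seed: int = 0
    grid_shape: tuple[int, int, int] | None = None
    csf_voxels: int = 200

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise CohortConfigError("n_subjects must be positive")
        f = self.inter_subject_fraction
        if not (0.0 <= f < 1.0):
            raise CohortConfigError("inter_subject_fraction must lie in [0, 1)")
        object.__setattr__(
            self, "residual_correlation", _as_correlation(self.residual_correlation)
        )
        if self.csf_voxels < 1:
            raise CohortConfigError("csf_voxels must be positive")

    def counts(self, names: list[str]) -> dict[str, int]:
        """Resolved per-structure voxel counts."""
        v = self.voxels_per_structure
        if isinstance(v, int):
            if v < 1:
                raise CohortConfigError("voxels_per_structure must be positive")
            return {n: v for n in names}
        missing = [n for n in names if n not in v]
        if missing:
            raise CohortConfigError(f"voxel counts missing for {missing}")
        if any(v[n] < 1 for n in names):
            raise CohortConfigError("voxel counts must be positive")
        return {n: int(v[n]) for n in names}


@dataclass
class SubjectVolumes:
    """Label volume, four co-registered maps and CSF mask of one subject."""

    subject_id: str
    labels: np.ndarray
    maps: dict[str, np.ndarray]
    csf_mask: np.ndarray
    seed: int

    def voxels_of(self, label: int) -> np.ndarray:
        """Flat indices (canonical lexicographic order) of one label."""
        return np.flatnonzero(self.labels.ravel() == label)


def _layout(config: CohortConfig, names: list[str]) -> tuple[tuple[int, int, int], dict[int, np.ndarray]]:
    """Assign each label a run of flat voxel indices inside its own slab.

    Each region occupies ``ceil(n / (rows*cols))`` whole slices and fills
    exactly its first ``n`` voxels in lexicographic (slice, row, col)
    order, so regions are pairwise disjoint axis-aligned blocks.
    """
    counts = config.counts(names)
    if config.grid_shape is not None:
        shape = tuple(int(x) for x in config.grid_shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise CohortConfigError("grid_shape must be 3 positive integers")
    else:
        shape = None

    rows, cols = (shape[1], shape[2]) if shape else (16, 16)
    per_slice = rows * cols
    regions: dict[int, np.ndarray] = {}
    z = 0
    all_counts = [(i + 1, counts[n]) for i, n in enumerate(names)]
    all_counts.append((CSF_LABEL, config.csf_voxels))
    for label, n in all_counts:
        n_slices = -(-n // per_slice)
        start = z * per_slice
        regions[label] = np.arange(start, start + n)
        z += n_slices
    if shape is None:
        shape = (z, rows, cols)
    elif z > shape[0]:
        raise GridSizeError(
            f"grid {shape} too small: need {z} slices of {rows}x{cols} "
            f"to place all structures disjointly"
        )
    return shape, regions


def sample_subject(
    specs: list[NucleusSpec], config: CohortConfig, subject_seed: int,
    subject_id: str = "sub-00",
) -> SubjectVolumes:
    """Draw one subject's label volume and four quantitative maps.

    For structure *k* and contrast *c* the subject-level VOI mean is
    ``mu_kc + f * sigma_kc * u_kc`` with the four ``u`` drawn jointly
    from N(0, R); voxel values add ``sqrt(1 - f^2) * sigma_kc * eps``
    with per-voxel ``eps ~ N(0, R)``. Deterministic given the seed.
    """
    names = [s.name for s in specs]
    shape, regions = _layout(config, names)
    rng = np.random.default_rng(subject_seed)
    f = config.inter_subject_fraction
    R = config.residual_correlation
    # Tiny jitter keeps the Cholesky factor defined for singular R.
    L = np.linalg.cholesky(R + 1e-12 * np.eye(4))

    n_vox = int(np.prod(shape))
    labels = np.zeros(n_vox, dtype=np.int16)
    maps = {c: np.zeros(n_vox, dtype=float) for c in CONTRASTS}

    mu = np.array([s.mean for s in specs])
    sd = np.array([s.sd for s in specs])
    for k, spec in enumerate(specs):
        idx = regions[k + 1]
        labels[idx] = k + 1
        u = L @ rng.standard_normal(4)
        m = mu[k] + f * sd[k] * u
        eps = rng.standard_normal((idx.size, 4)) @ L.T
        vox = m + np.sqrt(1.0 - f * f) * sd[k] * eps
        for j, c in enumerate(CONTRASTS):
            maps[c][idx] = vox[:, j]

    csf_idx = regions[CSF_LABEL]
    labels[csf_idx] = CSF_LABEL
    for c in CONTRASTS:
        maps[c][csf_idx] = rng.normal(_CSF_MEAN[c], _CSF_SD[c], csf_idx.size)

    labels = labels.reshape(shape)
    return SubjectVolumes(
        subject_id=subject_id,
        labels=labels,
        maps={c: maps[c].reshape(shape) for c in CONTRASTS},
        csf_mask=labels == CSF_LABEL,
        seed=subject_seed,
    )


def subject_seeds(config: CohortConfig) -> list[int]:
    """Deterministic per-subject seeds derived from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    state = ss.generate_state(config.n_subjects, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def generate_cohort(
    config: CohortConfig, specs: list[NucleusSpec] | None = None
) -> list[SubjectVolumes]:
    """Generate ``config.n_subjects`` subjects with derived seeds."""
    if specs is None:
        specs = load_reference_params()
    seeds = subject_seeds(config)
    return [
        sample_subject(specs, config, seed, subject_id=f"sub-{i:02d}")
        for i, seed in enumerate(seeds)
    ]


def generate_raw_mt_pair(
    subject: SubjectVolumes, m0_level: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize the raw MT-off / MT-on magnitude pair behind an MTR map.

    ``msat = m0 * (1 - MTR/100)`` voxel-wise, so the MTR computation
    inverts the pair exactly. The MT-off volume is flat at ``m0_level``.
    """
    if m0_level <= 0:
        raise ValueError("m0_level must be positive")
    mtr = subject.maps["mtr"]
    labeled = subject.labels > 0
    if np.any(mtr[labeled] >= 100.0):
        raise ValueError("MTR >= 100 p.u. on labeled voxels; cannot invert")
    m0 = np.full_like(mtr, float(m0_level))
    msat = m0 * (1.0 - mtr / 100.0)
    return m0, msat


def generate_raw_sodium(
    subject: SubjectVolumes, hidden_scale: float = 1.0
) -> np.ndarray:
    """Return the unreferenced sodium volume: ``hidden_scale`` x truth.

    CSF referencing of the result recovers the referenced map up to the
    sampling error of the empirical CSF mean.
    """
    if hidden_scale <= 0:
        raise ValueError("hidden_scale must be positive")
    if not subject.csf_mask.any():
        raise ValueError("subject has an empty CSF mask")
    return hidden_scale * subject.maps["na"]


# ---------------------------------------------------------------------------
# Residual-correlation calibration
# ---------------------------------------------------------------------------

def _pair_index(pair: tuple[str, str]) -> tuple[int, int]:
    i, j = CONTRASTS.index(pair[0]), CONTRASTS.index(pair[1])
    return (i, j) if i < j else (j, i)


def _between_within(specs: list[NucleusSpec], weights: np.ndarray):
    """Voxel-weighted between-structure covariance of the tabulated means
    and the weighted mean within-structure covariance scale."""
    M = np.array([s.mean for s in specs])
    S = np.array([s.sd for s in specs])
    w = weights / weights.sum()
    mu = w @ M
    B = ((M - mu).T * w) @ (M - mu)
    W = ((S[:, :, None] * S[:, None, :]) * w[:, None, None]).sum(axis=0)
    return B, W


def predicted_pooled_correlation(
    specs: list[NucleusSpec], config: CohortConfig
) -> np.ndarray:
    """Law-of-total-variance prediction of the pooled 4x4 correlation.

    Pooled covariance over all VOI voxels = between-structure covariance
    of the means (voxel-count weighted) + mean within-structure
    covariance ``sigma_c sigma_d R_cd``; independent of ``f``.
    """
    names = [s.name for s in specs]
    counts = config.counts(names)
    w = np.array([counts[n] for n in names], dtype=float)
    B, W = _between_within(specs, w)
    C = B + W * config.residual_correlation
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def _nearest_correlation(A: np.ndarray, iters: int = 60) -> np.ndarray:
    """Higham alternating projection onto unit-diagonal PSD matrices."""
    Y = A.copy()
    dS = np.zeros_like(A)
    for _ in range(iters):
        Rk = Y - dS
        vals, vecs = np.linalg.eigh(Rk)
        X = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        dS = X - Rk
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
    vals, vecs = np.linalg.eigh(Y)
    X = (vecs * np.clip(vals, 1e-10, None)) @ vecs.T
    d = np.sqrt(np.diag(X))
    return X / np.outer(d, d)


@dataclass
class CalibrationResult:
    """Outcome of the residual-correlation search.

    ``config`` carries the calibrated matrix; ``achieved`` the pooled
    correlations measured on a simulated cohort; ``deviations`` the
    per-pair absolute miss. Pairs whose target is geometrically
    unreachable (the voxel-weighted between-structure covariance of the
    tabulated means bounds the pooled value) are listed in
    ``infeasible`` and left at their closest attainable value.
    """

    config: CohortConfig
    targets: dict[tuple[str, str], float]
    achieved: dict[tuple[str, str], float]
    deviations: dict[tuple[str, str], float]
    infeasible: list[tuple[str, str]]
    n_iter: int
    tolerance: float

    @property
    def converged(self) -> bool:
        feasible = [p for p in self.targets if p not in self.infeasible]
        return all(self.deviations[p] <= self.tolerance for p in feasible)


def calibrate_residual_correlation(
    config: CohortConfig,
    targets: dict[tuple[str, str], float] | None = None,
    tolerance: float = 0.05,
    max_iter: int = 8,
    damping: float = 0.8,
    specs: list[NucleusSpec] | None = None,
) -> CalibrationResult:
    """Search for a residual correlation reproducing pooled targets.

    Starts from the closed-form solution implied by the law of total
    variance, then refines iteratively: simulate a cohort, measure the
    pooled correlations, nudge each off-diagonal entry toward its
    target, and project back to the nearest unit-diagonal PSD matrix.
    Deterministic (fixed internal seeds derived from ``config.seed``).

    Targets outside the attainable interval (the between-structure mean
    geometry fixes most of the pooled covariance) are reported as
    infeasible with their achieved values rather than raised, so a
    partially feasible target set still calibrates the feasible pairs.
    """
    from .voi import cohort_blocks, pooled_correlation

    if targets is None:
        targets = dict(PAPER_CORRELATIONS)
    for pair, t in targets.items():
        if not (-1.0 < t < 1.0):
            raise ValueError(f"target for {pair} outside (-1, 1): {t}")
    if specs is None:
        specs = load_reference_params()

    names = [s.name for s in specs]
    counts = config.counts(names)
    w = np.array([counts[n] for n in names], dtype=float)
    B, W = _between_within(specs, w)
    V = np.diag(B) + np.diag(W)

    tgt = {_pair_index(p): t for p, t in targets.items()}
    infeasible: list[tuple[str, str]] = []
    for pair, t in targets.items():
        i, j = _pair_index(pair)
        lo = (B[i, j] - W[i, j]) / np.sqrt(V[i] * V[j])
        hi = (B[i, j] + W[i, j]) / np.sqrt(V[i] * V[j])
        if not (lo - tolerance <= t <= hi + tolerance):
            infeasible.append(pair)

    # Closed-form start: R_ij = (r_ij sqrt(V_i V_j) - B_ij) / W_ij.
    R = np.array(config.residual_correlation, copy=True)
    for (i, j), t in tgt.items():
        R[i, j] = R[j, i] = np.clip(
            (t * np.sqrt(V[i] * V[j]) - B[i, j]) / W[i, j], -0.999, 0.999
        )
    R = _nearest_correlation(R)

    sim_seeds = np.random.SeedSequence(config.seed).generate_state(
        max_iter, dtype=np.uint32
    )

    def measure(Rtry: np.ndarray, seed: int) -> dict[tuple[int, int], float]:
        cfg = replace(config, residual_correlation=Rtry, seed=seed)
        blocks = cohort_blocks(generate_cohort(cfg, specs))
        out = {}
        for (i, j) in tgt:
            r = pooled_correlation(blocks, (CONTRASTS[i], CONTRASTS[j])).r
            out[(i, j)] = r
        return out

    achieved = measure(R, int(sim_seeds[0]) % 2**31)
    n_iter = 1
    for it in range(1, max_iter):
        dev = {p: abs(achieved[p] - tgt[p]) for p in tgt}
        if max(dev.values()) <= tolerance / 2:
            break
        Rnew = R.copy()
        for (i, j), t in tgt.items():
            step = damping * (t - achieved[(i, j)]) * np.sqrt(V[i] * V[j]) / W[i, j]
            Rnew[i, j] = Rnew[j, i] = np.clip(R[i, j] + step, -0.999, 0.999)
        Rnew = _nearest_correlation(Rnew)
        new_achieved = measure(Rnew, int(sim_seeds[it]) % 2**31)
        n_iter += 1
        new_dev = {p: abs(new_achieved[p] - tgt[p]) for p in tgt}
        feas = [p for p in tgt
                if (CONTRASTS[p[0]], CONTRASTS[p[1]]) not in infeasible
                and (CONTRASTS[p[1]], CONTRASTS[p[0]]) not in infeasible]
        if sum(new_dev[p] for p in feas) < sum(dev[p] for p in feas):
            R, achieved = Rnew, new_achieved
        else:
            break

    ach = {p: achieved[_pair_index(p)] for p in targets}
    devs = {p: abs(ach[p] - targets[p]) for p in targets}
    if infeasible:
        warnings.warn(
            "pooled-correlation targets infeasible for pairs "
            f"{infeasible}; achieved {[round(ach[p], 3) for p in infeasible]}",
            stacklevel=2,
        )
    return CalibrationResult(
        config=replace(config, residual_correlation=R),
        targets=dict(targets),
        achieved=ach,
        deviations=devs,
        infeasible=infeasible,
        n_iter=n_iter,
        tolerance=tolerance,
    )
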