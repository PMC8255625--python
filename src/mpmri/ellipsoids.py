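"""Tri-axial ellipsoid construction and pairwise overlap decisions.

Each structure is represented in (chi, MTR, T1) space by an axis-aligned
ellipsoid centered at its per-contrast means with semi-axes equal to the
per-contrast SDs; the mean sodium concentration rides along as a display
attribute (a color, not a fourth axis). Two closed ellipsoids overlap
iff some point satisfies both quadratic forms <= 1; the decision is made
exactly (to numerical tolerance) by minimizing one form over the other
ellipsoid via a 1-D root search on the Lagrange multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .voi import StructureSummary

__all__ = ["Ellipsoid", "make_ellipsoid", "overlap", "overlap_matrix"]

#: Contrasts spanning the three geometric axes, in axis order.
AXIS_CONTRASTS = ("qsm", "mtr", "t1")

_TOL = 1e-10


class DegenerateEllipsoidError(ValueError):
    """A zero SD collapses an axis."""


@dataclass(frozen=True)
class Ellipsoid:
    structure: str
    center: np.ndarray   # (chi ppm, MTR p.u., T1 ms)
    semi_axes: np.ndarray
    color_value: float   # mean sodium, mmol/l (display only)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.semi_axes) <= 0):
            raise DegenerateEllipsoidError(
                f"non-positive semi-axis for {self.structure!r}"
            )

    def quadratic(self, x: np.ndarray) -> np.ndarray:
        """Axis-aligned quadratic form; <= 1 inside the closed ellipsoid."""
        z = (np.asarray(x) - self.center) / self.semi_axes
        return np.sum(z * z, axis=-1)


def make_ellipsoid(summary: StructureSummary) -> Ellipsoid:
    """Build a structure's ellipsoid from its summary statistics."""
    center = np.array([summary.mean[c] for c in AXIS_CONTRASTS], dtype=float)
    axes = np.array([summary.sd[c] for c in AXIS_CONTRASTS], dtype=float)
    return Ellipsoid(
        structure=summary.structure,
        center=center,
        semi_axes=axes,
        color_value=summary.mean["na"],
    )


def overlap(e1: Ellipsoid, e2: Ellipsoid, max_iter: int = 200) -> tuple[bool, float]:
    """Decide whether two closed axis-aligned ellipsoids intersect.

    Returns ``(overlaps, margin)`` where ``margin = min Q2 - 1`` with
    the minimum of e2's quadratic form taken over e1; negative margin
    means overlap (tangency counts as overlap).

    Coordinates are first normalized to unit-SD coordinates of ``e1``
    (making e1 the unit ball), so the decision is scale-free across the
    disparate physical units of the three axes. In these coordinates the
    constrained minimizer on the unit sphere is
    ``x_i(lam) = d_i / (1 + lam * b_i^2)`` and the multiplier solves
    ``sum_i x_i(lam)^2 = 1`` -- a monotone 1-D root-finding problem.
    """
    d = (e2.center - e1.center) / e1.semi_axes
    b = e2.semi_axes / e1.semi_axes

    def q2(x: np.ndarray) -> float:
        return float(np.sum(((x - d) / b) ** 2))

    if float(np.sum(d * d)) <= 1.0 + _TOL:
        # e2's center lies inside e1: the unconstrained minimum (0) is
        # attained within the feasible set.
        min_q2 = 0.0
    else:
        def g(lam: float) -> float:
            x = d / (1.0 + lam * b**2)
            return float(np.sum(x * x)) - 1.0

        lo, hi = 0.0, 1.0
        it = 0
        while g(hi) > 0:
            hi *= 2.0
            it += 1
            if it > max_iter:
                raise RuntimeError(
                    f"overlap multiplier bracket failed: d={d}, b={b}"
                )
        lam = brentq(g, lo, hi, xtol=_TOL, maxiter=max_iter)
        x_star = d / (1.0 + lam * b**2)
        min_q2 = q2(x_star)
    margin = min_q2 - 1.0
    return margin <= _TOL, margin


def overlap_matrix(
    summaries: list[StructureSummary],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pairwise overlap decisions within one functional group.

    Returns structure names, a symmetric boolean matrix (diagonal true)
    and the symmetrized margin matrix (pairwise margins can differ by
    orientation; the minimum of the two directed margins is reported).
    """
    ells = [make_ellipsoid(s) for s in summaries]
    n = len(ells)
    names = [e.structure for e in ells]
    mat = np.eye(n, dtype=bool)
    margins = np.full((n, n), -1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ov_ij, m_ij = overlap(ells[i], ells[j])
            ov_ji, m_ji = overlap(ells[j], ells[i])
            ov = ov_ij or ov_ji
            m = min(m_ij, m_ji)
            mat[i, j] = mat[j, i] = ov
            margins[i, j] = margins[j, i] = m
    return names, mat, margins
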