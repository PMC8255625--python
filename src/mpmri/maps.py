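"""Derived quantitative map computation: MTR and CSF-referenced sodium.

Both operations are purely voxel-wise. MTR is the fractional signal drop
under off-resonance saturation expressed in percentage units; sodium
maps are scaled so that the CSF compartment averages the physiological
concentration of 140 mmol/l.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reference import CONTRAST_UNITS, CSF_SODIUM

__all__ = ["QuantMap", "compute_mtr", "reference_sodium"]


class MapShapeError(ValueError):
    """Input volumes disagree in shape."""


@dataclass
class QuantMap:
    """A quantitative 3D map with validity mask and units.

    ``values`` are guaranteed finite wherever ``mask`` is true.
    """

    values: np.ndarray
    contrast: str
    units: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise MapShapeError(
                f"values {self.values.shape} vs mask {self.mask.shape}"
            )
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside validity mask")
        expected = CONTRAST_UNITS.get(self.contrast)
        if expected is not None and self.units != expected:
            raise ValueError(
                f"units {self.units!r} inconsistent with contrast "
                f"{self.contrast!r} (expected {expected!r})"
            )


def compute_mtr(
    m0: np.ndarray, msat: np.ndarray, mask: np.ndarray | None = None
) -> QuantMap:
    """Magnetization transfer ratio from an MT-off / MT-on pair.

    ``MTR = (M0 - Msat) / M0 * 100`` (percentage units) on masked
    voxels. Voxels with non-positive M0 inside the mask are invalidated
    and counted in a warning rather than propagating infinities.
    Values outside [-100, 100] (possible with noise) are retained.
    """
    m0 = np.asarray(m0, dtype=float)
    msat = np.asarray(msat, dtype=float)
    if m0.shape != msat.shape:
        raise MapShapeError(f"m0 {m0.shape} vs msat {msat.shape}")
    if mask is None:
        mask = np.ones(m0.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != m0.shape:
        raise MapShapeError(f"mask {mask.shape} vs m0 {m0.shape}")

    valid = mask & (m0 > 0)
    n_bad = int(mask.sum() - valid.sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} masked voxels with non-positive M0 invalidated",
            stacklevel=2,
        )
    values = np.zeros_like(m0)
    values[valid] = (m0[valid] - msat[valid]) / m0[valid] * 100.0
    out_of_range = np.abs(values[valid]) > 100.0
    if valid.sum() and out_of_range.mean() > 0.01:
        warnings.warn(
            f"{out_of_range.mean():.1%} of valid voxels have |MTR| > 100 p.u.",
            stacklevel=2,
        )
    return QuantMap(values=values, contrast="mtr", units="p.u.", mask=valid)


def reference_sodium(raw: np.ndarray, csf_mask: np.ndarray) -> QuantMap:
    """Scale a raw sodium volume so the CSF mean equals 140 mmol/l.

    The whole volume is multiplied by ``140 / mean(raw over CSF)``; the
    output's CSF mean is therefore exactly the physiological reference
    (to machine precision). Idempotent.
    """
    raw = np.asarray(raw, dtype=float)
    csf_mask = np.asarray(csf_mask, dtype=bool)
    if raw.shape != csf_mask.shape:
        raise MapShapeError(f"raw {raw.shape} vs csf_mask {csf_mask.shape}")
    if not csf_mask.any():
        raise ValueError("empty CSF mask")
    if not np.all(np.isfinite(raw[csf_mask])):
        raise ValueError("non-finite raw values inside CSF mask")
    csf_mean = float(raw[csf_mask].mean())
    if csf_mean <= 0:
        raise ValueError(f"CSF mean must be positive, got {csf_mean}")
    values = raw * (CSF_SODIUM / csf_mean)
    mask = np.isfinite(values)
    return QuantMap(values=values, contrast="na", units="mmol/l", mask=mask)
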