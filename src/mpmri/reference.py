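"""Reference population parameters for 21 subcortical structures.

The packaged table carries, for each structure, its functional-group
assignment and the population mean and standard deviation of four
co-registered quantitative MR contrasts measured at 7T:

* ``qsm`` -- magnetic susceptibility chi (ppm),
* ``na``  -- tissue sodium concentration (mmol/l), CSF-referenced,
* ``mtr`` -- magnetization transfer ratio (percentage units),
* ``t1``  -- longitudinal relaxation time (ms).

These parameters drive the synthetic cohort generator and serve as the
ground truth against which cohort-level statistics are checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

#: Canonical contrast order used throughout the package.
CONTRASTS: tuple[str, ...] = ("qsm", "na", "mtr", "t1")

#: Physical units per contrast.
CONTRAST_UNITS: dict[str, str] = {
    "qsm": "ppm",
    "na": "mmol/l",
    "mtr": "p.u.",
    "t1": "ms",
}

#: The five functional groups.
FUNCTIONAL_GROUPS: tuple[str, ...] = (
    "epi_thalamic",
    "aras",
    "limbic",
    "extrapyramidal",
    "fiber_tract",
)

#: Structures too small to survive the low resolution of sodium imaging;
#: excluded by default from the classification tasks (partial volume).
DEFAULT_EXCLUDED: frozenset[str] = frozenset({"MB", "LC", "HB"})

#: Label value reserved for the CSF compartment in synthetic volumes.
CSF_LABEL = 22

#: Physiological CSF sodium concentration (mmol/l) used for referencing.
CSF_SODIUM = 140.0


class ReferenceDataError(RuntimeError):
    """Raised when the packaged parameter table is missing or corrupt."""


@dataclass(frozen=True)
class NucleusSpec:
    """Identity and per-contrast population statistics of one structure.

    Parameters
    ----------
    name : str
        Canonical abbreviation (e.g. ``"Pal"``).
    full_name : str
        Unabbreviated anatomical name.
    group : str
        One of :data:`FUNCTIONAL_GROUPS`.
    mean, sd : ndarray of shape (4,)
        Population mean and standard deviation in canonical contrast
        order (:data:`CONTRASTS`).
    """

    name: str
    full_name: str
    group: str
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in FUNCTIONAL_GROUPS:
            raise ReferenceDataError(
                f"unknown functional group {self.group!r} for {self.name!r}"
            )
        if np.any(np.asarray(self.sd) < 0):
            raise ReferenceDataError(f"negative SD for {self.name!r}")

    def mean_of(self, contrast: str) -> float:
        return float(self.mean[CONTRASTS.index(contrast)])

    def sd_of(self, contrast: str) -> float:
        return float(self.sd[CONTRASTS.index(contrast)])


def load_reference_params() -> list[NucleusSpec]:
    """Load the packaged per-structure parameter table.

    Returns
    -------
    list of NucleusSpec
        Exactly 21 specs in canonical table order (this order also fixes
        the integer label of each structure: index + 1).

    Raises
    ------
    ReferenceDataError
        If the packaged resource is missing or malformed.
    """
    try:
        text = (
            resources.files("mpmri.data")
            .joinpath("nucleus_params.tsv")
            .read_text(encoding="utf-8")
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ReferenceDataError("packaged nucleus_params.tsv not found") from exc

    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    expected = [
        "abbrev", "full_name", "group",
        "qsm_mean", "qsm_sd", "na_mean", "na_sd",
        "mtr_mean", "mtr_sd", "t1_mean", "t1_sd",
    ]
    if header != expected:
        raise ReferenceDataError(f"unexpected header in nucleus_params.tsv: {header}")

    specs: list[NucleusSpec] = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(expected):
            raise ReferenceDataError(f"malformed row: {ln!r}")
        abbrev, full_name, group = parts[0], parts[1], parts[2]
        vals = [float(v) for v in parts[3:]]
        mean = np.array(vals[0::2])
        sd = np.array(vals[1::2])
        specs.append(NucleusSpec(abbrev, full_name, group, mean, sd))

    names = [s.name for s in specs]
    if len(specs) != 21 or len(set(names)) != 21:
        raise ReferenceDataError(
            f"expected 21 uniquely named structures, got {len(specs)}"
        )
    return specs


def structure_names(specs: list[NucleusSpec] | None = None) -> list[str]:
    """Canonical structure abbreviations in table (= label) order."""
    if specs is None:
        specs = load_reference_params()
    return [s.name for s in specs]


def structure_labels(specs: list[NucleusSpec] | None = None) -> dict[str, int]:
    """Map structure abbreviation -> integer label (1-based, table order)."""
    return {name: i + 1 for i, name in enumerate(structure_names(specs))}


def spec_by_name(specs: list[NucleusSpec], name: str) -> NucleusSpec:
    """Look a spec up by abbreviation or full anatomical name."""
    for s in specs:
        if s.name == name or s.full_name == name:
            return s
    raise KeyError(f"no structure named {name!r}")
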