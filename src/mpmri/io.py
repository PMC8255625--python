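"""NIfTI and tabular I/O helpers.

Volumes travel as NIfTI-1 (float32 maps, integer labels, identity affine
by default); results as TSV with fixed column order, nested reports as
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CohortConfig, SubjectVolumes
from .reference import CONTRASTS
from .voi import CorrelationResult, StructureSummary

__all__ = [
    "read_nifti",
    "write_nifti",
    "write_subject",
    "read_subject",
    "write_cohort",
    "summaries_to_frame",
    "correlations_to_frame",
]


class NiftiIOError(IOError):
    """Malformed NIfTI input or inconsistent volume pair."""


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise NiftiIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    return np.asarray(img.dataobj), img.affine


def write_nifti(
    volume: np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
    dtype: type | None = None,
) -> Path:
    """Write a volume as NIfTI-1. Integer volumes keep an integer dtype;
    float volumes default to float32."""
    if affine is None:
        affine = np.eye(4)
    if dtype is None:
        dtype = np.int16 if np.issubdtype(volume.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(np.asarray(volume, dtype=dtype), affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def check_same_shape(a: np.ndarray, b: np.ndarray, what: str = "volumes") -> None:
    if a.shape != b.shape:
        raise NiftiIOError(f"{what} shapes disagree: {a.shape} vs {b.shape}")


def write_subject(subject: SubjectVolumes, outdir: str | Path) -> dict[str, str]:
    """Write one subject's labels, maps and CSF mask; returns file map."""
    outdir = Path(outdir)
    paths = {}
    paths["labels"] = str(write_nifti(subject.labels, outdir / "labels.nii.gz"))
    for c in CONTRASTS:
        paths[c] = str(write_nifti(subject.maps[c], outdir / f"{c}.nii.gz"))
    paths["csf_mask"] = str(
        write_nifti(subject.csf_mask.astype(np.uint8), outdir / "csf_mask.nii.gz")
    )
    return paths


def read_subject(paths: dict[str, str], subject_id: str, seed: int) -> SubjectVolumes:
    """Rebuild a SubjectVolumes from a manifest entry."""
    labels, _ = read_nifti(paths["labels"])
    maps = {}
    for c in CONTRASTS:
        vol, _ = read_nifti(paths[c])
        check_same_shape(labels, vol, f"labels vs {c} map")
        maps[c] = np.asarray(vol, dtype=float)
    csf, _ = read_nifti(paths["csf_mask"])
    return SubjectVolumes(
        subject_id=subject_id,
        labels=np.asarray(labels, dtype=np.int16),
        maps=maps,
        csf_mask=np.asarray(csf, dtype=bool),
        seed=seed,
    )


def write_cohort(
    cohort: list[SubjectVolumes], config: CohortConfig, outdir: str | Path
) -> Path:
    """Write all subjects plus a JSON manifest echoing the config."""
    outdir = Path(outdir)
    manifest = {
        "config": {
            "n_subjects": config.n_subjects,
            "inter_subject_fraction": config.inter_subject_fraction,
            "residual_correlation": np.asarray(
                config.residual_correlation
            ).tolist(),
            "seed": config.seed,
            "csf_voxels": config.csf_voxels,
            "voxels_per_structure": config.voxels_per_structure
            if isinstance(config.voxels_per_structure, int)
            else dict(config.voxels_per_structure),
        },
        "subjects": {},
    }
    for subject in cohort:
        paths = write_subject(subject, outdir / subject.subject_id)
        manifest["subjects"][subject.subject_id] = {
            "seed": subject.seed,
            "files": paths,
        }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def summaries_to_frame(summaries: list[StructureSummary]) -> pd.DataFrame:
    """One row per structure: per-contrast mean and SD plus voxel count."""
    rows = []
    for s in summaries:
        row = {"structure": s.structure, "scope": s.scope, "n_voxels": s.n_voxels}
        for c in CONTRASTS:
            row[f"{c}_mean"] = s.mean[c]
            row[f"{c}_sd"] = s.sd[c]
        rows.append(row)
    cols = ["structure", "scope", "n_voxels"] + [
        f"{c}_{m}" for c in CONTRASTS for m in ("mean", "sd")
    ]
    return pd.DataFrame(rows, columns=cols)


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    rows = [
        {"contrast_a": r.contrast_pair[0], "contrast_b": r.contrast_pair[1],
         "r": r.r, "p": r.p, "n": r.n}
        for r in results
    ]
    return pd.DataFrame(rows, columns=["contrast_a", "contrast_b", "r", "p", "n"])
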