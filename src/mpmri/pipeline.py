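"""End-to-end pipeline: generate -> maps -> stats -> features -> classify.

A single master seed deterministically derives every per-stage seed, so
a fixed configuration reproduces its artifact directory bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

from .classify import build_dataset, contrast_ablation, run_task
from .cohort import (
    CohortConfig,
    PAPER_CORRELATIONS,
    calibrate_residual_correlation,
    generate_cohort,
)
from .ellipsoids import overlap_matrix
from .features import feature_table
from .io import correlations_to_frame, summaries_to_frame, write_cohort
from .reference import (
    CONTRASTS,
    DEFAULT_EXCLUDED,
    FUNCTIONAL_GROUPS,
    load_reference_params,
)
from .voi import cohort_blocks, grand_means, pool_and_summarize, pooled_correlation

log = logging.getLogger("mpmri")

__all__ = ["PipelineConfig", "run_pipeline"]

_CONFIG_KEYS = {
    "n_subjects", "inter_subject_fraction", "seed", "csf_voxels",
    "voxels_per_structure", "calibrate", "n_runs", "cv", "ablation_cv",
    "ablation_runs", "excluded_structures", "run_ablation",
}


@dataclass
class PipelineConfig:
    """Serializable configuration of one full pipeline run."""

    n_subjects: int = 5
    inter_subject_fraction: float = 0.4
    seed: int = 0
    csf_voxels: int = 200
    voxels_per_structure: int | dict[str, int] | None = None
    calibrate: bool = True
    n_runs: int = 100
    cv: str = "loo"
    ablation_cv: str = "kfold5"
    ablation_runs: int = 100
    run_ablation: bool = True
    excluded_structures: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_EXCLUDED)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(
            n_subjects=self.n_subjects,
            inter_subject_fraction=self.inter_subject_fraction,
            seed=self.seed,
            csf_voxels=self.csf_voxels,
        )
        if self.voxels_per_structure is not None:
            kwargs["voxels_per_structure"] = self.voxels_per_structure
        return CohortConfig(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _log_stage(stage: str, payload: str) -> None:
    digest = hashlib.sha256(payload.encode()).hexdigest()[:12]
    log.info("stage=%s sha256=%s", stage, digest)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages; writes artifacts and returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = load_reference_params()

    # --- cohort -----------------------------------------------------------
    cohort_cfg = config.cohort_config()
    calibration_info = None
    if config.calibrate:
        calib_cfg = replace(cohort_cfg, seed=_stage_seed(config.seed, "calibrate"))
        result = calibrate_residual_correlation(calib_cfg, PAPER_CORRELATIONS)
        cohort_cfg = replace(result.config, seed=cohort_cfg.seed)
        calibration_info = {
            "achieved": {f"{a}-{b}": v for (a, b), v in result.achieved.items()},
            "infeasible": [f"{a}-{b}" for a, b in result.infeasible],
            "n_iter": result.n_iter,
        }
    cohort = generate_cohort(cohort_cfg, specs)
    write_cohort(cohort, cohort_cfg, outdir / "cohort")
    _log_stage("generate", str(cohort_cfg.seed))

    # --- VOI statistics ---------------------------------------------------
    blocks = cohort_blocks(cohort)
    by_structure: dict[str, list] = {}
    for b in blocks:
        by_structure.setdefault(b.structure, []).append(b)
    pooled = [pool_and_summarize(bs) for bs in by_structure.values()]
    summary_df = summaries_to_frame(pooled)
    summary_df.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    _log_stage("stats", summary_df.to_csv())

    corr = [
        pooled_correlation(blocks, (a, b))
        for a, b in combinations(CONTRASTS, 2)
    ]
    corr_df = correlations_to_frame(corr)
    corr_df.to_csv(outdir / "corr.tsv", sep="\t", index=False)

    gm = {
        subset: grand_means(pooled, subset, specs)
        for subset in ("nuclei", "fiber_tracts")
    }

    # --- ellipsoid overlap per functional group ---------------------------
    overlap_rows = []
    summaries_by_name = {s.structure: s for s in pooled}
    for grp in FUNCTIONAL_GROUPS:
        members = [s.name for s in specs if s.group == grp]
        names, mat, margins = overlap_matrix(
            [summaries_by_name[n] for n in members]
        )
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                overlap_rows.append(
                    {"group": grp, "a": names[i], "b": names[j],
                     "overlaps": bool(mat[i, j]),
                     "margin": float(margins[i, j])}
                )
    import pandas as pd
    pd.DataFrame(overlap_rows).to_csv(outdir / "overlap.tsv", sep="\t", index=False)

    # --- features ---------------------------------------------------------
    feats = feature_table(cohort, specs)
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False)
    _log_stage("features", feats.to_csv())

    # --- classification ---------------------------------------------------
    excluded = frozenset(config.excluded_structures)
    reports = {}
    task_seed = _stage_seed(config.seed, "classify")
    for task, group in [("all_structures", None), ("functional_groups", None)] + [
        ("within_group", g) for g in FUNCTIONAL_GROUPS
    ]:
        ft = build_dataset(feats, task, group=group, excluded=excluded)
        rep = run_task(ft, n_runs=config.n_runs, cv=config.cv, seed=task_seed)
        key = task if group is None else f"within_{group}"
        reports[key] = {
            "classes": rep.classes,
            "mean_accuracy": rep.mean_accuracy,
            "per_class_accuracy": rep.per_class_accuracy,
            "confusion": rep.confusion.tolist(),
            "importances": rep.importances,
            "contrast_importance": rep.contrast_importance,
            "n_runs": rep.n_runs,
            "cv": rep.cv,
        }

    ablation = None
    if config.run_ablation:
        abl = contrast_ablation(
            feats, n_runs=config.ablation_runs, cv=config.ablation_cv,
            seed=_stage_seed(config.seed, "ablate"), excluded=excluded,
        )
        ablation = {"+".join(k): v for k, v in abl.items()}
        pd.DataFrame(
            [{"subset": k, "mean_accuracy": v} for k, v in ablation.items()]
        ).to_csv(outdir / "ablation.tsv", sep="\t", index=False)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "calibration": calibration_info,
        "grand_means": {
            subset: {c: list(v) for c, v in gm[subset].items()}
            for subset in gm
        },
        "pooled_correlations": {
            f"{r.contrast_pair[0]}-{r.contrast_pair[1]}": r.r for r in corr
        },
        "tasks": reports,
        "ablation": ablation,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _log_stage("report", json.dumps(report, sort_keys=True))
    return outdir
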