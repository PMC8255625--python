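# mpmri

Multiparametric quantitative MRI characterization of subcortical
nuclei: a tested pipeline from co-registered quantitative maps (QSM,
sodium, MTR, T1) and VOI labels to per-structure statistics, ellipsoid
overlap geometry, first-order radiomic features, and random-forest
classification — plus a synthetic cohort generator parameterized by
published 7T per-structure statistics for when the underlying volunteer
data are not available.

## The problem

Deep gray-matter structures (basal ganglia, midbrain, brainstem nuclei)
carry characteristic multiparametric MR fingerprints: iron-rich
extrapyramidal nuclei show high magnetic susceptibility χ (ppm) and
short T1 (ms); CSF-adjacent structures show high tissue sodium
(mmol/l); macromolecule-dense regions show high magnetization transfer
ratio (p.u.). Given four co-registered quantitative maps and a label
volume of 21 structures in five functional groups — (epi-)thalamic,
ARAS, limbic, extrapyramidal, fiber tracts — the pipeline answers: how
well do the combined voxel-intrinsic values of one VOI identify the
structure (or its group)?

For a VOI with voxel values flattened to a 1-D signal x per contrast,
each sample is described by 8 first-order features per contrast
(32 total):

    mean(x), var(x), min(x), max(x),
    mean(∇x), var(∇x), min(∇x), max(∇x)

and classified by a 100-tree random forest under leave-one-out
cross-validation, averaged over re-seeded runs. Descriptive statistics
(per-structure mean ± SD, ascending rankings, grand means, pooled
voxel-wise Pearson correlations between contrasts) and a tri-axial
ellipsoid overlap analysis in (χ, MTR, T1) space complete the picture.

The synthetic generator draws each (structure, contrast) population as
Gaussian with the published mean and SD, split into a between-subject
fraction f of the SD and a within-VOI remainder, with one 4×4
correlation matrix R coupling the contrasts at both levels. R is
calibrated so the cohort's pooled voxel-wise correlations reproduce the
published values. See `docs/methods.md` for the model, its defaults and
its limits.

## Worked example

```python
from dataclasses import replace
from mpmri import (CohortConfig, calibrate_residual_correlation,
                   generate_cohort, feature_table, build_dataset,
                   run_task, pool_and_summarize, pooled_correlation)
from mpmri.voi import cohort_blocks

calib = calibrate_residual_correlation(CohortConfig(seed=0))
cfg = replace(calib.config, seed=0)
cohort = generate_cohort(cfg)          # 5 subjects, 21 labeled VOIs each
blocks = cohort_blocks(cohort)

pal = pool_and_summarize([b for b in blocks if b.structure == "Pal"])
print(pal.mean["qsm"], pal.sd["qsm"])  # 0.0844 0.0094  (target 0.0851 ± 0.0095)

r = pooled_correlation(blocks, ("t1", "na"))
print(round(r.r, 3), r.n)              # 0.572 8645     (target 0.58)

feats = feature_table(cohort)
ft = build_dataset(feats, "all_structures")   # 90 samples, 18 classes
rep = run_task(ft, n_runs=2, cv="loo", seed=0)
print(round(rep.mean_accuracy, 3))     # 0.994
print({k: round(v, 3) for k, v in rep.contrast_importance.items()})
# {'qsm': 0.278, 'na': 0.22, 'mtr': 0.221, 't1': 0.281}
```

The pooled globus pallidus (Pal) summary recovers its population
parameters within sampling error; the pooled T1–sodium correlation sits
within ±0.05 of the calibration target; the 18-structure task is nearly
perfectly solvable on this idealized cohort (synthetic Gaussian voxels
omit the partial-volume and segmentation noise of real data, so
accuracies sit above real-data figures); and susceptibility carries the
largest share of forest importance, consistent with its role as the
strongest single contrast for deep gray matter.

## Command line

```sh
mpmri generate --subjects 5 --seed 1 -o cohort/        # NIfTI volumes + manifest
mpmri maps mtr --m0 m0.nii.gz --msat msat.nii.gz -o mtr.nii.gz
mpmri maps sodium-ref --raw na.nii.gz --csf csf.nii.gz -o na_ref.nii.gz
mpmri stats summarize --map qsm=... --map na=... --map mtr=... --map t1=... \
      --labels labels.nii.gz -o summary.tsv
mpmri stats correlate --map ... --labels labels.nii.gz -o corr.tsv
mpmri ellipsoids --summary summary.tsv --group extrapyramidal -o overlap.tsv
mpmri features --cohort cohort/ -o features.tsv
mpmri classify --features features.tsv --task all --cv loo --runs 100 -o report/
mpmri ablate --features features.tsv -o ablation.tsv
mpmri run --seed 1 -o artifacts/                        # full pipeline
```

All volumes are NIfTI-1 (float32 maps, integer labels); tabular outputs
are TSV with fixed headers; nested reports are JSON stamped with the
config hash and seed.

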