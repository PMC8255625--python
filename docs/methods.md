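# Methods

## The problem this package models

Twenty-one subcortical gray-matter structures and fiber tracts (basal
ganglia, midbrain, brainstem and neighboring nuclei) were characterized
at 7T by four co-registered quantitative MR contrasts: magnetic
susceptibility χ from QSM (ppm), tissue sodium concentration (mmol/l,
referenced to CSF), magnetization transfer ratio (percentage units) and
T1 relaxation time (ms). The published per-structure means and SDs, the
functional-group taxonomy (epi-thalamic, ARAS, limbic, extrapyramidal,
fiber tracts) and the pooled cross-contrast correlations together define
a statistical fingerprint of each structure. This package re-implements
the downstream analysis as a tested pipeline and supplies a synthetic
cohort generator, parameterized by those printed statistics, in place of
the volunteer data (which were never deposited).

## Synthetic cohort model

Each (structure k, contrast c) population is Gaussian with the
tabulated mean μ_kc and SD σ_kc, decomposed hierarchically:

* subject-level VOI mean: m_kc = μ_kc + f·σ_kc·u, u ~ N(0, R)
* voxel value: m_kc + sqrt(1−f²)·σ_kc·ε, ε ~ N(0, R) per voxel

with f the between-subject fraction of total SD (default 0.4) and R a
single 4×4 unit-diagonal PSD correlation coupling the contrasts
identically at both levels. By the law of total variance the pooled SD
converges to σ_kc for every f, and the total within-structure
cross-contrast covariance is σ_kc·σ_kd·R_cd, independent of f. The
published table reports only pooled SDs, so the split into levels is a
modeling choice; f = 0.4 keeps the structure separations that the
reference reports as classifiable while giving subjects realistic
between-subject spread. Structures are laid out as disjoint axis-aligned
slabs on a regular grid with exact per-structure voxel counts; no
anatomical geometry is modeled because every downstream analysis
consumes voxel values only.

### VOI sizes

Default per-structure voxel counts are proportional to typical
anatomical volumes (putamen ≈ 4 cm³ down to millimetre-scale brainstem
nuclei), sampled at roughly 2 mm isotropic and floored at 10 voxels
(`DEFAULT_VOXEL_COUNTS`, ~1 700 voxels per subject). This matters
beyond realism: the pooled voxel-wise correlations weight structures by
voxel count. Under equal VOI sizes the voxel-weighted between-structure
covariance of the tabulated means caps the attainable pooled T1–sodium
correlation at ≈ 0.52 for *any* residual coupling R, below the
published 0.58; under anatomically proportional sizes the target is
comfortably inside the attainable interval. Equal sizes remain
available (`voxels_per_structure=200`).

### CSF compartment

A dedicated CSF label carries sodium N(140, 5²) mmol/l (the SD is not
published; 5 mmol/l is a plausible measurement spread) plus fluid-like
values for the other contrasts. It exists to exercise the sodium
referencing path; it is excluded from all VOI statistics.

### Residual-correlation calibration

`calibrate_residual_correlation` targets the five published pooled
correlations (T1–Na 0.58, T1–MTR −0.46, Na–MTR −0.25, T1–QSM −0.24,
MTR–QSM −0.01; Na–QSM was not published and is left free). The pooled
covariance decomposes exactly as B_cd + W_cd·R_cd, with B the
voxel-weighted between-structure covariance of the means and W the
weighted mean of σ_kc·σ_kd, giving a closed-form starting R. The search
then alternates simulate → nudge each entry toward its target → project
onto the nearest unit-diagonal PSD matrix (Higham alternating
projections), with a fixed iteration cap and seeds derived from the
config seed. Targets outside the attainable interval
[(B−W)/√(V_cV_d), (B+W)/√(V_cV_d)] are reported as infeasible with
their closest achieved value instead of raising: the T1–MTR target
−0.46 is such a case — the between-structure geometry of the tabulated
means forces the pooled value to ≈ −0.60 regardless of R. The four
feasible pairs calibrate to within ±0.05 (T1–Na typically within
±0.02).

## Derived maps

* MTR = (M0 − Msat)/M0 × 100 on masked voxels. Non-positive M0 voxels
  are invalidated and counted in a warning; values outside ±100 p.u.
  (possible with noise) are retained, with a warning if they exceed 1%
  of voxels. The operation is scale-invariant and voxel-wise.
* Sodium referencing multiplies the volume by 140 / mean(raw over the
  CSF mask), an arithmetic mean without trimming, so the output CSF
  mean is exactly 140 mmol/l and the operation is idempotent.

## VOI statistics

Per-structure voxel vectors are extracted in canonical lexicographic
(slice, row, column) order. Means are arithmetic; voxel-level SDs use
the sample denominator (n−1). Grand means across the 19 nuclei (or the
2 fiber tracts) are unweighted across structures, with the population
denominator (n) for the SD across structure means — the combination
that reproduces the published grand means to <0.2%. Pooled correlations
are Pearson r over all VOI voxels of all structures and subjects, with
the two-sided p from the exact t transform (n−2 df); no
multiple-testing correction is applied (none was in the reference
analysis).

## Ellipsoid overlap

Each structure maps to an axis-aligned ellipsoid in (χ, MTR, T1) space:
center = means, semi-axes = SDs, color attribute = mean sodium. Overlap
of closed ellipsoids is decided by minimizing one quadratic form over
the other ellipsoid: after normalizing to unit-SD coordinates of the
first ellipsoid (making the problem scale-free across ppm/p.u./ms), the
constrained minimizer on the unit sphere is x_i(λ) = d_i/(1 + λ·b_i²)
and the Lagrange multiplier solves a monotone 1-D equation, found by
Brent root search at 1e−10 tolerance. The margin is min Q₂ − 1
(negative ⇒ overlap; tangency counts as overlap). Note that the printed
two-decimal SDs make marginal pairs genuinely ambiguous: with the
tabulated values, RN–SN are clearly disjoint and RN–STN clearly
overlapping, while NC–Put — described qualitatively as overlapping —
come out just disjoint (margin +0.7, versus >5 for every other disjoint
extrapyramidal pair).

## Feature schema and classification

Each VOI is flattened to a 1-D signal per contrast in canonical voxel
order and summarized by 8 features — mean, variance (population
denominator), min, max of the signal and of its gradient — for 32
features per sample. The gradient uses central differences in the
interior and one-sided differences at the two endpoints (unit spacing),
with a forward-difference alternative via `gradient="forward"`. The
flattening order and gradient convention are reproducibility caveats:
they were not published, so gradient features of a reimplementation can
differ on real data; all statistical conclusions here rest on synthetic
data where the convention is fixed.

Three prediction tasks run on the feature table after excluding the
three smallest structures (MB, LC, HB; partial-volume-dominated at
sodium resolution): all 18 structures, the 5 functional groups, and
structures within each group. Nuclei from the same subject count as
independent samples. The classifier is a scikit-learn
RandomForestClassifier with 100 trees and otherwise default
hyperparameters (none beyond the tree count were published). Evaluation
is leave-one-out CV by default; the contrast-subset ablation uses
stratified 5-fold (both protocols appear in the reference description —
LOO in the methods text, 5-fold in the ablation figure — so both are
implemented and selectable). A "run" re-seeds the forest (and the fold
shuffle under k-fold) with the data fixed; reported accuracies are
means over runs. Confusion counts are summed over folds and runs and
then row-normalized, so the diagonal is per-class recall and the
overall accuracy equals the class-count-weighted mean of the per-class
accuracies exactly. Importances are mean impurity-decrease importances
of forests refit on the full data each run, normalized to sum 1;
per-contrast importance sums that contrast's 8 features.

## Problem sizes and determinism

The default cohort is 5 subjects × 21 structures (~8 600 VOI voxels).
Acceptance computations average the LOO tasks over 20 runs and the
ablation over 100 runs; the test suite uses 2–5 runs. The run average
is an unbiased Monte-Carlo estimate whose run-to-run SD is below one
percentage point on these tasks, so shorter averages estimate the same
quantity with slightly wider error. Every random draw derives from a
single master seed (numpy SeedSequence for subject seeds, `seed + run`
for forest seeds), making cohorts, reports and the full pipeline
bit-for-bit reproducible; identical seeds across ablation subsets make
subset accuracies directly comparable.

## What passing tests do and do not show

The generator produces spatially uncorrelated Gaussian voxels inside
geometrically trivial VOIs. It omits partial-volume mixing at structure
boundaries, segmentation error, registration misalignment, B0/B1
inhomogeneity, heavy-tailed or skewed intensity distributions, and
spatial autocorrelation — the error sources that dominate real data.
Classification accuracies on this cohort therefore sit *above* the
published real-data figures (e.g. the 18-structure task reaches ~95%
versus the published 85%), and per-class confusion patterns (such as
the MGB–LGB confusion) are not expected to reproduce. What the tests
establish is that the pipeline's statistics, geometry and protocols are
implemented correctly and that, under the published per-structure
parameters, the structures are separable to at least the published
degree.

## Known limitations

* The hierarchical split f and the shared inter-level coupling R are
  under-determined by the published pooled statistics; both are
  configurable but their defaults are conventions.
* The T1–MTR pooled correlation target is unattainable under the
  published per-structure means/SDs (see calibration above); the
  calibrator reports it as infeasible.
* Ellipsoid overlap decisions for marginal pairs depend on the printed
  rounding of the SDs.
* The fiber-tract sodium grand mean printed in the reference (42.4
  mmol/l) differs by 1.9% from the mean of its own two tabulated rows
  (43.2 mmol/l); the package reproduces the table-derived value.
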