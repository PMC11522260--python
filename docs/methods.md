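# Methods

This note documents the models, conventions and numerical choices behind
`perturbomics`, in the order the pipeline runs them.

## 1. Phantom cohorts

The generator emulates the kind of data the pipeline targets — a
segmented soft-tissue structure in a CT-like volume, two diagnostic
classes, a few dozen patients — without modelling anatomy. Each phantom
is an axis-aligned ellipsoid ROI (semi-axes sampled per patient from
configurable mm ranges) on a homogeneous zero background. The intensity
inside the ROI is

```
I(v) = base + b_p + shift_c + T_c(v)        (+ white noise everywhere)
```

with `base = 100`, a per-patient offset `b_p ~ N(0, 25)`, a class shift
`shift_c = texture_effect × 25` applied to class B only, and a textured
field `T_c` (Gaussian-filtered white noise, sd 50, in-plane correlation
length 1.5 voxels for class A and `1.5 × (1 + 0.2 × effect)` for class
B). `texture_effect` is therefore a Cohen's-d-like separation of the
class means in units of the between-patient spread, plus a correlated
change of texture scale; at 0 the classes are draws from the same
distribution, which is what makes the pipeline's null calibration test
meaningful. Default grid: 96×96×16 voxels at 1×1×2 mm; default white
noise sd 10 (a tenth of the intra-ROI texture spread, a moderately noisy
acquisition).

Generation verifies at build time that every ROI admits all four
perturbations (a ±30 % bounding-box translation margin on each in-plane
side); a cohort that cannot be perturbed is a configuration error, not a
runtime surprise. Cohorts are pure functions of their config (single
`numpy` Generator, fixed draw order), so a seed reproduces every voxel.

What the phantoms do **not** reproduce: anatomical shape variation,
intensity-calibrated Hounsfield semantics, bias fields, partial-volume
tissue interfaces, and — importantly — a structured background. The ROI
sits on empty surroundings, so a dilated ROI mixes in zeros rather than
neighbouring tissue. Passing tests on phantoms therefore demonstrates the
*mechanics* (exact-area perturbation, leakage safety, calibration of the
screens) rather than clinical performance; see §7.

## 2. Perturbation operators

All operators run slice-by-slice on the native-resolution mask, before
any resampling, and the 3D variant is reassembled from the perturbed
slices. Areas below are pixel counts per slice.

**Exact-area erosion/dilation.** The kernel is the 3×3 cross (a pixel
and its 4-neighbours). The target is `A_f = round(A_0 (1 + τ))` with
τ = −0.15/+0.15 for the stability ensemble and −0.30/+0.30 for the
augmentation ensemble. Whole kernel passes are applied while the next
pass would not overshoot the target; the residual is settled by a partial
pass: for erosion, boundary pixels are removed outermost-first (smallest
Euclidean distance-transform depth), so the innermost boundary survives;
for dilation, candidate ring pixels nearest the mask are added first.
Ties are broken in raster order, which makes the operators fully
deterministic. Slices below kernel scale (A₀ < 9 px, or target < 4 px)
pass through unperturbed with a logged warning — a 3×3 kernel has no
meaning below its own footprint.

**Contour randomization.** Each slice is partitioned into
`round(slice_area_mm² / superpixel_area_mm²)` SLIC superpixels computed
on the min-max-normalized intensities (compactness 0.1, connectivity
enforced). For each superpixel, ν = |superpixel ∩ ROI| / |superpixel|;
inclusion for ν ≥ 0.90, exclusion for ν ≤ 0.20, Bernoulli(ν) in between.
ν is measured against the ROI *region* (not the contour curve), and the
Bernoulli(ν) rule keeps the expected randomized area near the original.
Two guard rails at the volume level: a slice smaller than one superpixel
passes through unperturbed (the operator is undefined below its atomic
unit — with 4 cm² augmentation superpixels this is common near the
ellipsoid poles), and if every borderline draw fails the
highest-overlap borderline superpixel is kept so the ROI never comes
back empty. The slice-level function keeps strict error semantics for
direct use.

**Translation.** The whole 3D mask shifts in-plane by
`round(0.30 × bbox_extent)` pixels along ±x or ±y, where the bounding
box is the tight box of the full 3D mask (a single rigid shift — a
per-slice box would shear the stack). Shifting out of the grid raises an
error; clipping would silently change the area the translation is
defined to preserve.

## 3. Preprocessing and features

Images are denoised with a Gaussian (σ = 0.5 voxels, truncated to the
3×3×3 kernel), optionally z-scored (MR-like intensities only), and
resampled to 2 mm isotropic with B-spline interpolation; masks follow by
nearest-neighbour. Perturbation happens *before* this stage: 25 mm²
superpixels are sub-7-pixel objects on a 2 mm grid, so perturbing after
resampling would be degenerate.

The feature registry is the standard 107-vector: 14 shape, 18
first-order, and 75 texture features (24 GLCM, 16 GLRLM, 16 GLSZM,
5 NGTDM, 14 GLDM), computed from the standardized matrix definitions.
Conventions that matter:

* Discretization: fixed bin width, 25 intensity units for CT-like and
  0.1 standardized units for MR-like images;
  level = `floor(x/w) − floor(min/w) + 1`.
* GLCM and GLRLM are computed per 3D direction (13 unique angles at
  Chebyshev distance 1) and feature values averaged over directions;
  GLCM matrices are symmetrized. Zones (GLSZM) and neighbourhoods
  (NGTDM, GLDM) use 26-connectivity; GLDM uses dependence tolerance
  α = 0 and dependence size = dependent neighbours + 1.
* Shape meshes come from marching cubes on the Gaussian-smoothed
  (σ = 1 voxel) binary indicator: the raw 0.5-level set of a binary
  volume is a staircase whose area overestimates the true surface by
  ≈ 8 %, which would bias sphericity irrecoverably; with smoothing a
  radius-10-voxel sphere scores sphericity within 0.5 % of 1 (mesh
  volume trades ≈ 3 % accuracy at that radius, converging with size).
  First-order moments are population moments; kurtosis is not
  excess-corrected.
* Feature extraction is 3D over the reassembled perturbed volume.

`build_feature_table` denoises/resamples each patient's image once and
resamples every mask variant onto that one grid, so all variants of a
patient share an identical intensity field — and a (patient, variant)
row can be looked up later without re-extraction.

## 4. Robustness screen

Only the 93 first-order/texture features are scored; shape features are
deliberately altered by every perturbation, so perturbation-derived rows
would carry corrupted shape values — they bypass the screen and are
dropped from the downstream pool.

The agreement statistic is the one-way random-effects, single-measurement
ICC — ICC(1,1) = (MSB − MSW) / (MSB + (k−1) MSW) — because perturbation
replicates have no rater identity that a two-way model could use.
Stability uses patients × {original, eroded, dilated, randomized}
(threshold: ICC > 0.75, strict); discrimination uses patients ×
{original, 4 translations} (ICC < 0.5, strict). A zero-variance feature
returns ICC = 1 by convention (logged): constant replicates are perfect
agreement. The screen runs once on the whole cohort, before
cross-validation, consistent with treating robustness as a property of
the feature under the imaging/segmentation process rather than of a
training split.

## 5. Selection, resampling, classification

Per training fold, in order: Spearman redundancy filter → resampling →
relevance selector → z-scoring → linear SVM (C = 1, uniform class
weights — class balance is the resampler's job, and with ≤ ~30 candidate
features a linear kernel is the defensible default).

* **Redundancy**: greedy elimination — while any pair exceeds the
  threshold (0.90 or 0.95), take the currently worst pair and drop the
  member with the higher mean |ρ| against all remaining features;
  descending-|ρ| processing makes the order deterministic, and equal
  means keep the earlier registry feature. Constant features have
  undefined ρ, treated as 0 (logged).
* **Mann–Whitney selector**: two-sided, α = 0.05, unadjusted — the
  permissive end of the selector family, by design.
* **LASSO**: L1 logistic path over 20 penalties, inner stratified 5-fold
  CV on log-loss, one-standard-error rule (strongest penalty within one
  SE of the best), nonzero coefficients selected. An all-zero fit is an
  explicit failure state, not an empty success.
* **PCA**: eigendecomposition of the training correlation matrix, Kaiser
  retention (eigenvalue > 1, minimum 1 component); loadings, means and
  scales are frozen into the fitted model so test rows are projected
  with training statistics only. The semi-supervised variants prefilter
  with Mann–Whitney and run LASSO/PCA on the survivors.
* **Resamplers**: ROS duplicates rows; SMOTE interpolates uniformly
  toward one of the k = 5 nearest within-class neighbours (distances in
  the training-fold z-scored space, interpolation in raw feature
  space); ADASYN allocates the budget across class samples
  proportionally to the fraction of other-class samples among their k
  nearest all-class neighbours (largest-remainder rounding; uniform
  fallback when every neighbourhood is pure). Balance mode equalizes
  counts; augment mode brings each class to exactly 4× (processed
  per class, within-class neighbours).
* **Perturbation balancing** draws minority patients without replacement
  until exhausted (then with replacement), picks a perturbation kind
  uniformly among that patient's unused kinds, and never reuses a
  (patient, kind) pair — the deficit is capped at 3× the minority
  patient count. **Perturbation augmentation** appends all three variant
  rows per training instance. Both operate purely by lookup into the
  precomputed variant table: deterministic, fast, and a clean leakage
  boundary (the variant table is filtered to training patients before it
  enters the fold).

Folds are stratified with a fixed global seed; per-fold seeds are
derived arithmetically, so a run is reproducible end-to-end. A selector
failure marks the fold failed with its reason and the run continues;
failed folds are excluded from summary means but always reported.

Method comparison: fold-wise difference vectors are checked with
Shapiro–Wilk (α = 0.05); if none rejects, repeated-measures ANOVA with
paired-t post-hocs, otherwise a Friedman omnibus with Dunn's
within-block-rank z post-hocs. Pairwise p-values are Holm-adjusted.
Identical metric vectors across methods short-circuit to p = 1.

## 6. Calibration of the end-to-end tests

The pipeline-level tests use cohorts of 20 patients per class (the scale
of the clinical problem this tooling targets), 10-fold stratified CV,
and a reduced feature registry (first-order + GLCM, 42 features) to keep
the full matrix affordable; the registry subset changes nothing
structural. "Null" is `texture_effect = 0`; "strong effect" is
`texture_effect = 3` (a 3-SD class separation). Over 10 cohort seeds the
null arm must stay within [0.35, 0.65] mean balanced accuracy, the
strong-effect augmented arm above 0.9, and augmentation must not cost
more than 0.05 balanced accuracy against the no-augmentation arm on the
across-seed means — a loose regression guard, not a superiority claim;
single-seed comparisons at 4 test samples per fold are dominated by fold
noise.

## 7. Known limitations

* The phantoms' empty background makes large dilations (|τ| = 0.30) mix
  zeros into the ROI, which perturbs intensity features harder than
  dilation into real neighbouring tissue would; augmentation on phantoms
  is correspondingly conservative about the method's benefit.
* At phantom ROI sizes (≈ 5 cm² maximal slice), 4 cm² augmentation
  superpixels exceed many slice areas, so the randomized augmentation
  variant often equals the original on small slices (logged).
* The ICC screen is a point decision at fixed thresholds; no confidence
  intervals or alternative agreement metrics (CCC, CoV) are computed.
* SVM hyperparameters are not tuned; the benchmark compares resampling
  strategies under a fixed classifier, not maximal achievable accuracy.
* Shape features never re-enter the candidate pool after the screen;
  variant rows would carry misleading shape values if they did.
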