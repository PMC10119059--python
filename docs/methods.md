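# Methods

## The problem

PET delineations are conventionally binary: a voxel is either inside
the tumor volume of interest or not. At lesion boundaries this is a
poor model of the data — the scanner's point spread function (PSF)
mixes tumor and background signal over a distance of roughly one FWHM
(4.6–5 mm for typical PET systems), and manual delineations carry
their own uncertainty on the same scale. Fuzzy radiomics keeps the
standard IBSI feature definitions but lets every voxel carry a
membership weight in [0, 1], so a PSF-matched soft boundary can enter
the feature computation directly. Classic radiomics is the special
case where all weights are 0 or 1.

This package implements the weighted extraction engine, the four
delineation variants used to compare binary against fuzzy analysis,
and the downstream comparison machinery (harmonization, redundancy
reduction, harmonized Monte-Carlo cross-validation, evaluation), all
exercised end to end on synthetic phantoms.

## Delineation variants

From a reference binary mask (Ref-B) on the 2 mm isotropic analysis
grid:

* **Ref-F** = Ref-B convolved with a normalized 3D Gaussian whose FWHM
  equals the system resolution (σ = FWHM / 2√(2 ln 2); separable
  kernel truncated at 4σ). Convolution with a normalized kernel
  conserves total membership mass for lesions ≥ ~3σ from the array
  border (verified to 1e-6 relative) and never leaves [0, 1].
* **Ext-B** = Ref-B dilated by a Euclidean ball of radius 3 voxels
  (123 lattice points for a single seed voxel). A ball radius — rather
  than 3 iterations of a cross — is the reading of "3 voxels in 3D"
  adopted here; both radius and structuring element are configurable.
* **Ext-F** = the fuzzified Ext-B.

Masks and volumes must share grids exactly; variants are generated on
the analysis grid, so the FWHM→σ conversion uses 2 mm spacing by
default. Lesions with fewer than 64 reference-mask voxels are excluded
before variant generation (the gate grid is configurable because the
alternative — gating on the acquisition grid — is equally defensible).

## The weighted engine

Discretization is fixed-bin-size on TBR values (default width 0.1
TBR), with the minimum *included* intensity as bin origin. A voxel is
included when its membership exceeds ε = 1e-3; ε is the only threshold
in the weighted path, so features are continuous in the weights
elsewhere.

How memberships enter the intermediate matrices:

* **GLCM** — a co-occurring pair (a, b) contributes w_a·w_b
  (configurable to the arithmetic mean). The product preserves
  bilinearity and binary equivalence.
* **GLRLM / GLSZM** — a run or 26-connected zone contributes the mean
  membership of its member voxels (configurable to the product). The
  mean avoids the collapse of long runs that a product would cause.
* **NGTDM** — each voxel contributes w_k·|g_k − Ā_k| to its level's
  deviation sum, where Ā_k is the membership-weighted mean level of
  its included 26-neighbors; per-level occurrence masses are
  membership sums. Voxels without included neighbors are excluded
  from the occurrence masses.

First-order statistics use the memberships as frequency weights with
population (Σw) denominators; weighted quantiles follow the
inverse-empirical-CDF rule, which reduces to
`np.percentile(..., method="inverted_cdf")` at unit weights.

Two deliberate normalization conventions, applied identically in the
binary special case:

* NGTDM deviation sums enter the ratio features divided by the total
  occurrence mass (s_i/N). For contrast and complexity this coincides
  with the standard printed formulas; for coarseness, busyness and
  strength it differs by a fixed factor of N and makes all five
  features invariant under uniform weight scaling, which is the
  natural requirement for a membership-weighted definition (doubling
  all memberships conveys no new information).
* The intensity-histogram gradient is taken on the mass-normalized
  histogram for the same reason.

Mesh morphology (volume, area and derived shape descriptors) is
computed on the 0.5-level isosurface of the membership field via
marching cubes. The field is zero-padded and smoothed with a
0.8-voxel Gaussian before meshing: without anti-aliasing, the
staircase surface of a binary mask inflates the area by ~10% and
biases every area-derived descriptor (a digital 10 mm sphere then
reads sphericity ≈ 0.91 rather than ≈ 0.99). A fuzzy mask whose
maximum membership never reaches 0.5 has no isosurface; its mesh
features are flagged invalid rather than silently dropped. The
weighted voxel volume Σw·v_voxel is exact and needs no mesh.

### Feature manifest

The default manifest lists 153 features: 9 morphology, 18 intensity
statistics, 23 intensity histogram, 25 GLCM × 2 aggregations, 16 GLRLM
× 2 aggregations, 16 GLSZM, 5 NGTDM. The two aggregations (average of
per-direction normalized matrices over the 13 unique 3D directions,
and merged-then-normalized) are counted as distinct features, in line
with aggregation variants being distinct feature definitions. Each
entry declares a weight-scaling class — *intensive* (invariant under
uniform weight scaling), *extensive* (proportional to it), or
*geometric* (tied to the 0.5-level set) — and the class is tested.
The manifest is editable (`save_manifest`/`load_manifest`, a
tab-separated text format); the engine emits exactly the listed
features in the listed order, with per-feature validity flags.

## Image I/O, resampling, TBR

Volumes and masks are NIfTI (nibabel); grids must coincide exactly (no
registration). Resampling to the 2 mm analysis grid offers ordinary
kriging and trilinear interpolation. The kriging predictor uses a
fixed isotropic Gaussian covariance (range 1.25 input-voxel units,
relative nugget 1e-10) solved in the 5³-node neighborhood of each
query point, with weights computed once per unique fractional offset;
queries coinciding with input nodes are copied exactly. A fixed
covariance was chosen over locally fitted variograms because fitting
on a smooth field in a 5³ window is ill-posed and would make the
interpolant input-dependent in fragile ways; trilinear interpolation
is retained as a cross-check (the two agree to <2% of the field range
on smooth fields away from the boundary). Masks are resampled with the
same operator, clamped to [0, 1], and binary masks re-thresholded at
0.5. TBR normalization divides by the arithmetic mean inside the
background mask, after resampling; it is idempotent and commutes with
uniform rescaling.

## Synthetic cohorts

The phantom generator defines the study conditions; no clinical data
ships with the package.

* **Geometry** — axis-perturbed ellipsoids (per-axis radii jittered
  ±20%), mean radius uniform in 6–14 mm, rasterized on the 2 mm grid
  (≈100–1400 voxels, matching the small-lesion regime where fuzzy
  analysis matters most). Lesions under the 64-voxel gate are redrawn.
* **Texture** — a stationary Gaussian random field (white noise
  smoothed to a 6 mm correlation length), standardized, then scaled
  by a lesion-level contrast parameter and added to a lesion-level
  mean uptake. The correlation length directly controls how much
  signal the texture families see.
* **Class effect** — the lesion-level mean uptake (TBR ~ N(4.0, 0.8))
  and texture contrast (N(0.8, 0.15)) are both shifted by
  `label_effect_size` standard deviations for the positive class, so
  intensity and texture features carry signal; effect 0 is an exact
  null.
* **Physics** — isotropic Gaussian PSF blur (default FWHM 5 mm,
  glioma-like) plus additive Gaussian noise (SD 0.05 TBR).
* **Background** — a 2-voxel-thick shell at ≥3 PSF-FWHM from the
  lesion, guaranteeing a partial-volume-free TBR denominator.
* **Cohort structure** — default 84 lesions with 39% minority
  (glioma-like counts); labels are assigned per patient, and a
  configurable lesions-per-patient distribution produces prostate-like
  multi-lesion patients.

What the phantoms do *not* emulate: anatomy, scanner reconstruction
(sinograms, iterative reconstruction artifacts), respiratory motion,
inter-observer delineation variability, or correlated multi-modal
channels. Passing tests therefore demonstrate that the pipeline is
correct and well-calibrated under its own assumptions, not that the
clinical effect sizes are reproduced.

## Cross-validation and models

* 100 Monte-Carlo folds, 90/10 train-test; per-class test size =
  max(1, ⌊0.10 · minority count⌋), so every test set is exactly
  balanced. Test lesions are drawn patient-wise (patients are sampled
  per class until the lesion quota is met exactly, with bounded
  redraws), folds must be unique, and the identical fold list is
  reused for every delineation table.
* Within each fold the selected features are z-scored on training
  statistics before balancing and model fitting: raw radiomic features
  span many orders of magnitude, and both SMOTE's nearest-neighbor
  geometry and the multi-Gaussian covariance shrinkage are
  scale-sensitive (random forests are unaffected).
* Training sets are balanced by SMOTE (synthetic minority rows as
  convex combinations of k = min(5, minority−1) nearest minority
  neighbors; originals preserved).
* Features are ranked by univariate R² (squared point-biserial
  correlation, zero-variance → 0, ties by name) and the top
  f = ⌈√(0.9·2·M)⌉ are kept, M being the cohort's majority-class
  count before oversampling. The ceiling is the only rounding that
  reproduces all three published per-cohort budgets (45→9, 51→10,
  204→20); using the cohort-level M (rather than the slightly smaller
  per-fold training M) likewise matches those printed counts.
* The classifier is a fixed-hyperparameter ensemble: four random
  forests differing in tree count, depth, per-split feature fraction
  and leaf size (100/∞/√, 150/8/√, 75/∞/0.5, 125/12/log2 with leaf
  sizes 1/2/1/3 — placeholder defaults, configurable), plus one
  multi-Gaussian classifier (per-class ML mean and covariance with
  ridge shrinkage λ = 1e-3·trace/d, equal priors since training is
  balanced). Prediction is the majority of the 5 votes; the vote
  fraction (∈ {0, .2, .4, .6, .8, 1}) is the ROC score. Five voters
  make ties impossible. No per-fold tuning, no dimensionality
  reduction.
* All randomness flows from one master seed through named substreams
  (cohort, folds, per-fold SMOTE/model seeds), so a run is a pure
  function of its configuration.

## Harmonization and redundancy reduction

A feature is dropped from all four tables when, in any table, it is
invalid for every lesion or constant over its valid values (two or
more values required to call "no variation"); then any lesion with a
remaining invalid cell in any table is dropped from all four; the two
rules iterate to a fixed point, making the result independent of rule
order. Redundancy reduction connects feature pairs with |Spearman ρ|
≥ 0.9 (inclusive, as the threshold's strictness is not prescribed),
takes connected components as clusters — transitive closure rather
than greedy pruning, so the result is order-invariant — and keeps the
highest raw-variance member of each cluster (ties by name). It is
idempotent and applied per delineation table before cross-validation.

## Evaluation

Per-fold confusion counts and rank-based (Mann-Whitney, half-credit
ties) AUC; CV summaries report the mean per-fold AUC with a normal
95% CI (±1.96·SD/√n_folds), the pooled-score AUC, and pooled confusion
metrics. Zero-denominator metrics are NaN, never 0. Because test sets
are balanced, pooled accuracy equals balanced accuracy exactly.
Delineations are compared by one-way ANOVA of per-fold AUCs, reference
binary versus each alternative (p = 1 by convention when both groups
have zero variance). The volume analysis restricts pooled predictions
to a closed common volume range (938–354,987 mm³ for the published
cohorts; 938 mm³ ≈ 117 voxels at 2 mm), cuts the restricted volume
distribution into 10 percentile clusters (boundary lesions to the
lower decile), and reports per-(delineation, decile) lesion counts,
correct-classification counts and — separately labelled — per-decile
AUC, since "aggregate performance" can reasonably mean either.

## Problem sizes and numerical notes

The shipped acceptance-level checks run an 84-lesion cohort with 100
folds for all four delineations (the full comparison twice: once with
effect size 1.0, once with an exact null); unit tests use 12–30-lesion
cohorts and ≤200-voxel lesions. The binary-equivalence oracle compares
all 153 features on 25 random lesions against an independently coded
unweighted implementation at 1e-10 relative tolerance. Degenerate
inputs (single grey level, missing isosurface, undefined denominators)
produce flagged NaNs, never silent drops; empty masks, empty
backgrounds and single-class folds raise typed errors.

## Known limitations

* The exact identity of the published 153-feature list is not public;
  the default manifest is this package's reconstruction from the
  stated families and consensus levels, and is editable.
* The published per-matrix weight-incorporation formulas are not
  public either; the product/mean schemes here are this package's
  choices (config-switchable), constrained by binary equivalence.
* RF/MG hyperparameters are representative defaults, not the
  originals.
* On these phantoms the fuzzy-vs-binary redundancy direction reported
  for clinical cohorts does **not** reproduce: the PSF-matched fuzzy
  mask includes a large low-weight halo, so every feature picks up the
  same lesion-to-background contrast factor and the fuzzy tables come
  out *more* mutually correlated than the binary ones. Clinical data
  plausibly behaves differently because down-weighting noisy boundary
  voxels removes a shared noise component that the phantoms (with
  their single-factor texture model) do not possess. The directional
  check is kept as an acceptance-level assertion and documents this
  divergence rather than hiding it.
* Redundancy on the phantoms is extreme in absolute terms as well —
  of ~152 harmonized features, connected-component clustering at
  |ρ| ≥ 0.9 leaves only ~10–20 survivors (clinical tables retain
  23–52) — because lesion-level mean uptake, texture contrast and
  size drive nearly every feature monotonically.
* Kriging with a fixed Gaussian covariance is a deterministic
  interpolant, not a geostatistical fit; on fields with strong
  anisotropy it has no advantage over trilinear interpolation.
* The CV summary's 95% CI (±1.96·SD/√n_folds) treats Monte-Carlo fold
  AUCs as independent. They are not — folds share most of their
  training data and re-test the same lesions — so the interval
  understates the cohort-level uncertainty of the mean CV AUC. For an
  84-lesion cohort the cohort-level SD of the mean null AUC is roughly
  0.05, larger than the ≈0.04 half-width of the 100-fold interval;
  a null cohort can therefore land outside the interval without any
  defect in the pipeline. Permutation tests or patient-level
  bootstraps are the appropriate tool when calibrated coverage
  matters; the interval is reported because it is the field's
  reporting convention.
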