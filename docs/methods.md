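# Methods

`restoselect` implements a texture-based pipeline for five-class,
image-level classification of dental restorations (filling, implant,
root-canal treatment, bridge, crown) on panoramic radiographs, with a
hybrid grey-wolf / particle-swarm (HGWO-PSO) wrapper selecting the
texture features that feed an RBF-kernel SVM. This note records the
model, its assumptions, the numerical conventions, and what the
synthetic phantom data can and cannot demonstrate.

## Enhancement chain

Radiographs are processed as integer grayscale matrices at native bit
depth (8 or 16). The chain is: centered crop → global histogram
equalization (HE) → contrast-limited adaptive histogram equalization
(CLAHE).

* **Crop.** Panoramic frames carry non-diagnostic peripheral margins;
  the default crop takes the centered 1700×880 window from a 2775×1504
  frame, with offsets `floor((src − target)/2)`. Cropping applies per
  axis only where the source exceeds the target, so small synthetic
  images pass through whole. No padding is ever performed.
* **Global HE** uses the textbook full-range CDF mapping
  `round((cdf(v) − cdf_min)/(N − cdf_min) · (L−1))` with `cdf_min` the
  CDF at the lowest occupied level. The mapping is monotone (rank
  preserving) and idempotent up to one gray level of rounding.
* **CLAHE** (clip 2.0, 8×8 grid by default) interprets the clip limit
  in the common "multiple of the uniform tile histogram height"
  convention: a tile of n pixels over L bins is clipped at
  `clip · n / L` counts, with the excess redistributed uniformly over
  all bins in one pass. Per-tile mappings use the same full-range CDF
  convention as global HE and are blended bilinearly between tile
  centers (nearest-tile beyond the outer centers), so a single
  unclipped tile reproduces global HE exactly. Other CLAHE dialects
  (e.g. skimage's normalized clip fraction) differ in the clip
  normalization; this one was chosen so that the clip→∞, 1×1-grid
  limit degenerates cleanly and the parameter reads as "how many times
  a flat histogram".

## Texture features

Each image is reduced to 25 gray-level co-occurrence (GLCM) features.
Pixels are min-max rescaled per image to [0, 1] and uniformly binned
into 64 levels (`floor(x·64)` clipped to 63; a constant image maps to
level 0). For each of the four unit displacements — 0°=(0,+1),
45°=(−1,+1), 90°=(−1,0), 135°=(−1,−1) in (row, col), borders truncated —
the co-occurrence counts are symmetrized (transpose added) and
normalized to a probability matrix p. Five descriptors are computed per
angle, plus their four-angle arithmetic mean:

* contrast `Σ p(i,j)(i−j)²`
* correlation `Σ p(i,j)(i−μx)(j−μy)/(σxσy)`, defined as 1 when
  `σxσy = 0` (a constant texture is perfectly predictable)
* ASM / energy `Σ p(i,j)²`
* homogeneity `Σ p(i,j)/(1+|i−j|)`
* entropy `−Σ p log₂ p` over nonzero cells (bits; any other base only
  rescales)

The canonical 25-column order is descriptor-major — Contrast,
Correlation, ASM, Homogeneity, Entropy — and within each descriptor
0°, 45°, 90°, 135° followed by the bare-named angle average
(`Contrast0 … Contrast135, Contrast, Correlation0, …`). Feature
columns are z-score standardized before classification; the
standardizer is fitted on training rows only, and a zero-variance
column maps to 0. The GLCM accumulation itself is delegated to
`skimage.feature.graycomatrix`; because that library measures angles
with rows increasing in the sine direction, our 45° corresponds to its
3π/4 and our 135° to its π/4 under symmetry. The test suite checks the
full 25-vector against an independent brute-force pair-enumeration
oracle at 1e−9.

## HGWO-PSO wrapper selection

Feature subsets are binary masks over the 25 columns, scored by the
wrapper fitness

    F = 0.9 · Acc + 0.1 · (1 − Fr)

where `Acc` is the mean stratified 3-fold cross-validated accuracy of
the downstream SVM on the selected columns (folds and classifier seed
fixed per run, so F is a pure, cached function of the mask) and
`Fr = |mask|/25` is the fraction of features kept — the second term is
explicit parsimony pressure. An empty mask is never evaluated; it
scores 0 and is flagged invalid.

The search hybridizes the grey-wolf leader hierarchy with the PSO
velocity rule. Each of the 10 agents carries a continuous position
X ∈ ℝ²⁵, a velocity V, and a mask. Per iteration:

1. every agent's mask is evaluated (cache-aware) and personal bests
   are updated;
2. the three leaders α/β/δ are re-ranked over the current agents plus
   the retained elites — replacement only by strictly better,
   mask-distinct agents, which makes the best-so-far history
   non-decreasing by construction;
3. all non-leader agents move by
   `V ← wV + c₁r₁(Pbest − X) + c₂r₂(Gbest − X)`, `X ← X + V`, with
   per-dimension uniform r₁, r₂, c₁ = c₂ = 2, and w annealed linearly
   0.8 → 0.4 over the run;
4. masks are re-drawn per dimension with the S-shaped transfer
   probability `sigmoid(Xⱼ)`; an all-zero draw is resampled once, then
   the dimension with the largest probability is forced on.

Numerical choices that mattered:

* **Gbest = mean of the three leader positions** (default
  `leader_combine="mean3"`). With the α-position alone the swarm
  collapses onto a single attractor and, on a d=10 planted-optimum
  benchmark with an exhaustive-enumeration oracle, recovers the global
  optimum in only ~60–85% of seeded runs; the leaders' centroid — the
  closer reading of the grey-wolf "follow α/β/δ" behavior — lifts this
  to ~95%. `"alpha"` remains available.
* **Velocities are clamped to ±6** so the sigmoid stays responsive.
* **Initial positions are the softened logit ±1** of the Bernoulli(0.5)
  initial mask (the exact logit of a binary mask is ±∞, which would
  freeze early exploration); `init_scale` is configurable.
* The position update is read as the standard PSO pair (velocity
  update, then `X(t+1) = X(t) + V(t+1)`); a literal assignment of the
  velocity expression to the position would discard position history.
* A deterministic 0.5-threshold binarization is available
  (`binarize="threshold"`) but the stochastic transfer is the default.

## Classifier bank

All conventional models are scikit-learn estimators behind thin
training functions: RBF-SVM with C = 10, γ = 0.1 and inverse-frequency
class weights (grid search over C ∈ {0.1, 1, 10, 100},
γ ∈ {0.001, 0.01, 0.1, 1} when enabled, ties broken toward the
smallest C then γ); K-NN with k tuned over the odd grid 3–11 (default
k = 5); a Gini decision tree of depth ≤ 20; a 100-tree random forest
of depth ≤ 20. Class weighting applies both inside the wrapper fitness
and in the final models. A CNN baseline is intentionally out of the
package's dependency footprint; the comparison bank is the
texture-feature family.

## Evaluation protocol

Splitting is at the patient level throughout: a seeded 80/20
train/test split assigns whole patients greedily (interleaved across
dominant per-patient labels as best-effort stratification) until the
test image count is closest to 20%, and the training patients are
partitioned into 5 folds by greedy longest-processing-time balancing
of image counts, which bounds the fold-size spread by the largest
per-patient count. Selection, standardization and hyperparameter
tuning are re-done inside each training fold; the final model is
fitted on the whole training side (its selection run uses the full
training set — fold-wise masks are logged in the report) and assessed
once on the held-out patients.

Metrics: overall accuracy is trace/total of the 5×5 confusion matrix
(equal to the per-class one-vs-rest (TP+TN)/(TP+TN+FP+FN) micro form);
per-class precision/recall/F1 use the 0/0 → 0 convention; macro
metrics average over all five classes including absent ones.
Uncertainty is a stratified bootstrap (1000 replicates, strata = true
class, percentile 95% intervals) over the aggregated test predictions.
Fold-level accuracies of two models are compared with a two-sided
paired t-test (all-zero differences → p = 1; constant nonzero
differences → t = ±∞ with a warning). Cohen's κ
`(p₀ − pₑ)/(1 − pₑ)` is provided for dual annotations, defined as 1
when both raters produce the same constant labeling.

## Synthetic phantoms

The generator emulates the *statistical structure* of a single-center
panoramic dataset, not its anatomy: per-patient grouping with a
multiplicative background gain (SD 6%) that correlates images within a
patient, five imbalanced classes (default priors 0.30/0.15/0.20/
0.15/0.20 for filling/implant/root-canal/bridge/crown), one dominant
label per image, and bright high-density inserts mimicking how
metallic restorations render: one hard-edged disk (implant), one
smooth compact blob (crown), an elongated bar (bridge), several small
speckles (filling), thin near-vertical streaks (root canal). The
background is a Gaussian random field (white noise blurred with a
σ = 4 px Gaussian, ≈ 8 px correlation length, mean 90, SD 8 on the
8-bit scale); component contrast scales linearly with `effect_size`
(default 2.5, so class signals vanish exactly at 0). The default
dataset is 24 patients × 6 images = 144 images of 128×128 px — sized
so a full benchmark runs in minutes on one CPU while keeping ≥ 100
images and all five classes populated.

Calibration contract (tested): at `effect_size ≥ 2` an RBF-SVM on the
25 standardized features reaches ≥ 0.60 held-out accuracy under a
patient-level 80/20 split (chance = largest prior ≤ 0.30); at
`effect_size = 0` accuracy falls back to the majority-class band.
Because speckles add high-frequency gray-level transitions while a
single disk is smooth, the filling class has the highest mean GLCM
contrast — frozen as a generator regression test.

What passing on phantoms does *not* show: robustness to real anatomy,
device- or exposure-dependent intensity scales, beam-hardening
artifacts, multiple coexisting restorations, or label noise. The
phantoms validate the machinery (leakage-safe protocol, selection
dynamics, metric arithmetic), not clinical performance.

## Experiment orchestration and determinism

`run_experiment` derives every stage seed (split, per-fold fits, final
fits, bootstrap) from one experiment seed via `SeedSequence`, so a
rerun with the same seed reproduces the report byte-for-byte. The
experiment default uses a 30-iteration optimizer preset; the
100-iteration benchmark setting is one config field away
(`HgwoPsoConfig()`), and the reported problem sizes (144 images,
30 iterations, B = 1000) are the package's default study conditions.
An audit hook receives the image ids entering every standardizer fit,
fitness-evaluator construction, grid search and final fit; the test
suite uses it to prove that held-out rows never participate in model
building.

## Known limitations

* Whole-image (global) GLCMs let background texture into the features
  by design; ROI- or patch-based extraction is out of scope.
* The wrapper fitness inherits the variance of 3-fold CV on small
  folds; with ~100 training images the selected mask varies across
  folds (all fold masks are logged rather than consolidated).
* The greedy patient split optimizes the test-fraction target, not
  exact class stratification; the achieved balance depends on the
  manifest.
* 16-bit inputs are supported end to end, but CLAHE builds 65536-bin
  tile histograms, which is memory-heavier than the 8-bit path.
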