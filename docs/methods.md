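# Methods

This note records the models, conventions and design choices behind
`morphocensus`, in the spirit of a statistical software appendix: what each
stage assumes, which knobs matter, and what the synthetic validation does
and does not demonstrate.

## Synthetic histology and cohorts

**Tiles.** Each 512 × 512 tile is rendered through the Beer-Lambert model
`I = 255 · 10^(−S·c)` with a fixed 3 × 2 optical-density mixing matrix `S`
whose columns are the classic hematoxylin and eosin OD anchors
(H ≈ (0.650, 0.704, 0.286), E ≈ (0.072, 0.990, 0.105), unit-normalized).
Cells are filled ellipses with per-cell hematoxylin concentration
(N(0.75, 0.08); small-hyperchromatic cells N(1.35, 0.10)); each cell carries
an eosinophilic cytoplasm rim (eosin ≈ U(1.5, 1.9)). The rim matters: the
Macenko angle estimator needs eosin-dominant pixels above the tissue OD
threshold, exactly as real cytoplasm provides; without it the eosin
direction is unidentifiable from nuclei alone. Stroma is rendered weakly
eosinophilic (≈0.22) and falls below the tissue threshold, as pale
background does in real slides.

Cell geometry: normal cell areas are lognormal (`area_mu`, `area_sigma`;
median = exp(`area_mu`), default 600 px² at 0.25 µm/px); axis ratios are
N(`ecc_mean`, 0.25) clipped at 1; small-hyperchromatic cells are drawn
small (U(120, 420) px²) and round (ratio U(1.0, 1.8)). Placement is
rejection sampling with 40 retries per cell against a bounding-circle
overlap rule; a configurable fraction of cells (default 5%) is allowed to
touch so instance splitting is exercised. Over-dense specifications
degrade gracefully to fewer placed cells. Every tile is deterministic in
`(seed, slide_id, tile_index)` via a hierarchical seed sequence, so any
subset of a cohort regenerates identically.

**Cohorts.** Each patient has a latent high/low-risk class; event times are
exponential with rate `baseline_hazard` (× `hazard_ratio` when high-risk),
censoring is Uniform(0, `censor_window`) years, and metastasis is generated
analogously with its own rates. The `effect_map` assigns class-specific
values to chosen slide parameters, which is the only path from class to
image — with an empty map, morphology is independent of outcome by
construction (tested by permutation). AJCC stage is drawn with a
class-dependent Stage-III probability so the stage baseline is informative
but far from perfect.

**What the generator does not emulate:** texture inside nuclei, chromatin
patterns, overlapping tissue layers, scanner blur/JPEG artifacts, spatially
correlated microenvironments, or specific melanoma growth patterns. Passing
tests therefore demonstrate the *correctness and calibration of the
pipeline's computations*, not segmentation or prognostic performance on
real H&E slides.

## Preprocessing

Tiling crops squares of `round(512 · 0.25 / mpp)` source pixels on a
non-overlapping grid from the top-left origin, drops partial edge tiles,
and resizes to 512 × 512 (bilinear; anti-aliased when downscaling).
Background rules operate on pooled statistics over all 3 × 512 × 512
values: drop at mean ≥ 230 (white), ≤ 40 (black) or SD < 20 (featureless).
The stricter scanner-specific set drops patches whose red mean is ≤ 90% of
the blue mean, whose green mean exceeds 210 while red is ≥ 170 (white), or
whose pooled mean is ≤ 40; the three published criteria are combined as a
disjunction of individually testable rules, applied after the generic
filter.

Stain normalization follows Macenko: OD = −log10(max(I,1)/255), pixels with
any channel at or below β = 0.15 OD excluded, SVD plane of the remaining
pixels, stain rays at the 1st/99th percentiles of the projection angle
(α = 1), sign-fixed nonnegative, hematoxylin identified as the column with
the larger blue-channel OD. Concentrations are unconstrained least squares;
robust maxima are the 99th percentile. The shipped reference model uses the
same OD anchors with reference maxima (1.30, 1.95), chosen as an
approximate fixed point of the estimator on well-stained synthetic tiles so
that normalizing an already-normalized tile changes it by well under one
intensity level on average. Patches with fewer than 200 tissue pixels raise
"insufficient tissue" and are skipped by the pipeline.

## Segmentation and morphometry

The built-in segmenter thresholds the hematoxylin concentration channel
(Gaussian σ = 1.5, Otsu), removes objects under 30 px, fills holes, and
splits touching cells by a distance-transform watershed with local-maximum
markers (minimum peak distance 7 px). Border-touching instances are kept.
Any external instance segmenter (e.g. a learned model) can be substituted
by providing masks in the same consecutive-integer label format.

Axis lengths use the equal-second-moment ellipse with the +1/12 per-pixel
spread correction: with pixel-coordinate central moments
u = cov + diag(1/12), axis length = 4·√(eigenvalue). A single pixel thus
measures 4·√(1/12) ≈ 1.155 rather than 0, a 40 × 10 rectangle has axis
ratio exactly 4, and measures are rotation-invariant to within rasterization
error. Delaunay neighbor distances are computed per patch (the patch is the
processing unit throughout); two-point and collinear configurations fall
back to all-pairs adjacency.

The small-hyperchromatic rule is area < 450 px² AND axis ratio < 2 AND mean
pooled RGB below an intensity threshold. No absolute darkness cutoff is
inherent to the category, so the default threshold is the 40th percentile
of per-cell mean intensity within the slide — adaptive to staining depth —
and an absolute override is accepted. The sparse-patch rule keeps patches
with at least `cutoff` cells (default 15; boundary inclusive, matching
"fewer than the cutoff are removed").

## The 135-feature census

Bin models are 1-D Lloyd k-means (k-means++ seeding, 10 restarts) per
distribution on values pooled with equal weight from up to 50 randomly
sampled slides; centroids are sorted. Distributions with fewer than 10
unique values are padded above their maximum with strictly increasing
offsets and flagged degenerate, so assignment never lands in a padded bin.
Values are assigned to the nearest centroid with ties to the lower index.

The five statistics are computed on the raw values (population moments,
n denominator): skewness g1 = m₃/m₂^1.5 and kurtosis m₄/m₂² in the Pearson
convention (normal → 3); both are defined as 0 when the variance vanishes.
Entropy is Shannon entropy in nats of the 10 bin proportions (0·ln 0 = 0,
maximum ln 10). Raw-value moments were chosen over histogram-based moments
because the centroids would needlessly coarsen them; the histogram enters
through the bin proportions and entropy. Bin proportions per distribution
sum to one, so each 15-block is internally consistent. Feature order is
fixed: for each of the 9 distributions, bins 1–10 then the 5 statistics;
cell-level blocks first (105 features), small-hyperchromatic blocks last
(30 features). Patient vectors are elementwise means over slides.

## Univariate cutoff scanning

100 candidate cutoffs are evenly spaced strictly inside the feature's
observed range; "high" is value > cutoff. Cutoffs leaving a stratum below
max(5, 10% of the cohort) are skipped. The log-rank statistic is a
vectorized pooled-risk-set computation (validated against an independent
implementation to 1e-6); groups with no events return p = 1 with a warning.
BH adjustment runs across the valid cutoffs within each feature — the best
cutoff's adjusted p is what the null simulation calibrates (empirical
type-I ≈ 0.04 at nominal 0.05 over 1000 null features, n = 100) — and a
second BH pass across features' best raw p-values is reported for
transparency, since selection optimism can be controlled on either axis.

## Risk labels and classifiers

Survival endpoint: high = death within 5 years; low = follow-up reaching
5 years without death; censored before 5 years = excluded from training and
testing. Metastasis endpoint: high = metastasis at any time; low =
metastasis-free follow-up reaching 5 years. The LASSO-Cox path (Breslow
ties, internal z-scoring, coefficients reported on the original scale) is
cross-validated by patient-disjoint folds for Harrell concordance;
`alpha_min` maximizes the mean, `alpha_1se` is the largest penalty within
one standard error. Gating is fitted once on the full labeled cohort before
classifier CV, matching the sequential protocol; the optimistic bias this
shares with the published procedure is noted here rather than hidden.

Classifier CV uses patient-disjoint folds (sizes within one), upsamples the
training-fold minority class with replacement to the majority count
(training folds only, to avoid test leakage), concatenates held-out
predictions across folds, and scores sensitivity/specificity/F1 with high
risk positive. Hyperparameters, unstated in the protocol this reproduces,
are fixed and logged: KNN k = 5; SVM RBF, C = 1; random forest 500 trees;
logistic with an L2 ridge of 1e-4 for numerical stability. Logistic
per-fold coefficients are retained for interpretability; "strong" features
(|fold-mean| > fold SD) are the ones whose directions are compared across
runs, since weaker coefficients flip by noise. With collinear selected bins
a multivariate coefficient can legitimately oppose its marginal class
direction (a suppressor), so planted-direction checks focus on the
dominant coefficient while the full agreement fraction is reported.

## Validation experiments (`experiments.py`)

The end-to-end study cohort plants smaller cells (median area 400 vs 650
px²) and a higher small-hyperchromatic fraction (0.30 vs 0.08) in the
high-risk class, hazard ratio 4, low-risk hazard 0.125/yr, uniform
censoring over 12 years, 200 patients at 60% high-risk prevalence, one
slide of two tiles each. The prevalence and hazards were set by a design
calculation before running the experiment: with exponential event times a
5-year binary label is a noisy readout of the latent class (a hazard ratio
of 4 cannot make both classes' labels pure), and these values give an
expected ceiling F1 ≈ 0.84 for a classifier that recovers the latent class
perfectly — so the ≥ 0.8 recovery bar tests the pipeline, not the
irreducible label noise. Problem sizes throughout (two tiles per slide,
50-seed recovery runs, 1000-feature null scans) are chosen so the whole
validation executes in minutes on one CPU.

## Known limitations

- The classical segmenter under-splits heavily overlapping cells and has no
  notion of nucleus vs cytoplasm; it measures whole segmented objects.
- The eosin stain direction is estimated from eosin-dominant mixtures, not
  pure eosin (pure-eosin pixels fall below the OD threshold in the red
  channel); a consistent small angular bias is therefore expected and
  absorbed by the fixed reference.
- LASSO gating before classifier CV leaks selection information; fold-inner
  refitting would be the conservative variant.
- Synthetic validation does not speak to StarDist-grade segmentation
  accuracy, real staining variability, or real-cohort prognostic
  performance.
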