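# morphocensus

Interpretable cell-morphology "census" features from H&E histology tiles,
with univariate Kaplan-Meier cutoff scanning and LASSO-Cox-gated
multivariate five-year risk classification.

Digital pathology risk models are often black boxes. This package takes the
opposite route: every feature it feeds a survival model is a named,
pathologist-readable statement about cells — how large they are, how
elongated, how densely packed, and how many small, darkly stained
(hyperchromatic) cells a slide contains. It is aimed at computational
pathology researchers who want a fully transparent baseline pipeline from
RGB tiles to survival-stratifying features, together with the statistical
machinery (cutoff scans, penalized Cox gating, balanced patient-disjoint
cross-validation) used to evaluate such features. Because real whole-slide
cohorts cannot ship with a package, a first-class synthetic-histology module
generates H&E-like tiles with ground-truth instance masks and clinical
cohorts whose hazard is planted in the morphology, so the entire pipeline is
testable end to end.

## The pipeline

1. **Preprocess** (`preprocess`): slides are tiled into 512 × 512 patches at
   0.25 µm/px (crop side `round(512 · 0.25 / mpp)` source pixels, then
   resized); background patches are dropped by pooled-RGB rules (mean ≥ 230,
   mean ≤ 40, SD < 20, plus a stricter rule set for bluish-background
   scanners); staining is normalized by Macenko's method — stain vectors are
   the extreme percentile rays of tissue pixels projected onto the leading
   SVD plane in optical-density space.
2. **Tumor triage** (`tumor_region`, optional): a pluggable patch classifier
   restricts the census to tumor patches; the built-in baseline is a
   logistic model on ~20 per-patch summary descriptors, and any external
   scorer (e.g. a CNN) can be wrapped with `ExternalPatchScorer`.
3. **Cell measurement** (`cell_features`): cells are instance-segmented
   (hematoxylin-channel Otsu + distance-transform watershed, or an external
   segmenter via the same mask format); patches with fewer than 15 cells are
   dropped; each cell gets area, moments-ellipse major/minor axes, axis
   ratio, mean RGB, and min/max/mean Euclidean distance to its Delaunay
   neighbors. Cells with area < 450 px², axis ratio < 2 and dark staining
   are flagged *small-hyperchromatic* (SHC; a proxy for lymphocytes and
   pyknotic nuclei), counted per patch.
4. **Census** (`census`): for each of 9 distributions (7 cell-level: area,
   major axis, minor axis, axis ratio, Delaunay min/max/mean; 2 patch-level:
   SHC count and density) a cohort-wide 1-D k-means model (k = 10, fitted
   once on up to 50 sampled slides) defines histogram bins. A slide is
   described by 10 bin proportions + 5 statistics (mean, SD, skewness,
   kurtosis, entropy) per distribution: 9 × 15 = **135 named features**
   (105 cell-morphology + 30 SHC). Patients with several slides get the
   elementwise mean.
5. **Univariate survival** (`survival`): each feature is scanned over 100
   cutoffs strictly inside its range; each cutoff splits the cohort and is
   tested by a two-group log-rank test; Benjamini-Hochberg adjustment is
   applied across cutoffs within a feature, with a second pass across
   features.
6. **Risk models** (`risk`): patients are labeled high/low risk for
   five-year survival (or metastasis at any time); censored-before-horizon
   patients are excluded. An L1-penalized Cox path with cross-validated
   Harrell concordance yields "min" and "1se" feature sets; logistic, KNN,
   RBF-SVM and random-forest classifiers are evaluated by patient-disjoint
   five-fold CV with minority-class upsampling in training folds only, and
   compared against the AJCC-stage baseline (Stage III ⇒ high risk).

## Worked example

```python
import numpy as np
import morphocensus as mc

cfg = mc.CohortConfig(
    n_patients=30, n_tiles=2, cell_density=90, seed=5,
    baseline_hazard=0.08, hazard_ratio=4.0, censor_window=12,
    effect_map={"area_mu": (np.log(650), np.log(400)),
                "shc_fraction": (0.08, 0.30)},
)
cohort = mc.generate_cohort(cfg)
feats = mc.extract_cohort_features(cohort, seed=5)
print(feats.features.shape)

merged = feats.features.join(
    cohort.clinical.set_index("patient_id")["latent_class"])
print(merged.groupby("latent_class")[["area_mean", "shc_density_mean"]].mean())
```

prints

```
(30, 135)
               area_mean  shc_density_mean
latent_class
high          381.515038          0.337884
low           636.258771          0.132610
```

Each of the 30 patients got a 135-feature census vector; the planted
high-risk class (median cell area 400 px², 30% SHC) is recovered as a mean
measured cell area of ~382 px² versus ~636 for the low-risk class, and an
SHC density of ~0.34 versus ~0.13 — the separation the downstream survival
models feed on. From here, `scan_feature_matrix` ranks features by their best
log-rank cutoff and `lasso_cox_path` + `evaluate_classifiers` produce the
gated five-year risk classifiers.

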