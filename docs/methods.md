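# Methods

`adnexrad` implements a complete ultrasound-radiomics workflow for
discriminating benign from malignant adnexal masses, exercised end-to-end on
a synthetic cohort generator. This note documents the models, the
parameters that matter, the numerical conventions, and what the synthetic
validation does and does not demonstrate.

## Pipeline

1. **Despeckling.** Each 2-D grayscale frame is filtered with a 3×3 adaptive
   local Wiener filter: per pixel, output = m + max(v−ν,0)/max(v,ν)·(x−m),
   with m and v the local window mean and variance and ν (the noise-variance
   estimate) the mean of all local variances. Edges use symmetric padding;
   output is clipped to the input dtype's range. The filter is idempotent on
   constant images and never raises global variance on stationary noise.
   The full image is despeckled before any ROI cropping.
2. **Per-ROI Z-scoring.** Intensities inside the lesion mask are
   standardized by the ROI mean and *sample* SD (n−1). Pixels outside the
   mask never enter any computation. Z-scoring makes every downstream
   feature exactly invariant to global gain/offset (scanner) transforms; a
   constant ROI is a hard `DegenerateROIError` because every texture feature
   would be undefined.
3. **Feature extraction.** 74 named features: 17 intensity statistics
   (population moments; kurtosis is excess kurtosis μ₄/μ₂²−3), 25 GLCM, 16
   GLRLM and 16 GLSZM features. Discretization is fixed-bin-number over the
   ROI's [min, max] with 32 bins (a config knob, recorded in every feature
   vector); the bin label is ⌈N·(x−min)/range⌉ clamped to [1, N], so the
   minimum maps to bin 1 and the maximum to bin N. GLCM: distance-1 pairs in
   the four 2-D directions, symmetrized and summed (merged) over directions
   before features. GLRLM: maximal runs per direction, merged over the four
   directions; run percentage divides by 4·n_pixels accordingly. GLSZM:
   8-connected constant-level zones, direction-free. All entropies use
   log₂. Guards: information correlation 2 = √(1−exp(−2(HXY2−HXY))) is
   floored at 0; GLCM correlation is defined as 1 for a single-level matrix;
   inverse variance sums off-diagonal cells only.
   No morphological/shape features (single 2-D frames) and no NGTDM family:
   the four families above already total 74.
4. **Selection.** Per-feature two-tailed Mann–Whitney U on the training
   split (exact enumeration when both groups ≤ 8, otherwise normal
   approximation with tie and continuity correction), Benjamini–Hochberg
   step-up at α = 0.05, then greedy Pearson pruning: features visited by
   ascending raw p (ties by registry order) and accepted iff |r| ≤ 0.6
   against all accepted features, so the lowest-p member of any correlated
   group survives. Pearson is computed on raw training features (it is
   affine-invariant, so scaling is immaterial). If nothing survives BH (a
   null cohort), the selector keeps the single best-ranked feature with a
   warning so downstream stages stay runnable. MRMR (greedy
   |point-biserial r| relevance minus mean |r| redundancy) and RFE are
   provided as alternates for overfitting checks.
5. **Scaling and modeling.** Selected features are Z-scaled with training
   statistics (sample SD) frozen for validation. Four algorithm families are
   supported for the radiomics-only model (penalized logistic, random
   forest, gradient-boosted trees/XGBoost, SVM). The clinical–radiomics
   variant adds age (years) and serum CA 125 (U/mL); CA 125 is missing for
   ~25% of cases and is never imputed, so this variant is restricted to the
   tree learners, which route missing values natively — non-tree algorithms
   refuse matrices containing NaN. Hyperparameters are tuned by randomized
   search (default 25 draws) over modest documented grids (tree depth 2–6
   for boosting, learning rate 0.01–0.3 log-spaced, 100–600 trees, L1/L2
   penalties log-spaced, RBF/linear kernels) with stratified 5-fold CV
   selecting on mean CV AUC, then refit on the full training split. All
   randomness is seeded.
6. **Split.** 70:30 stratified over the five histology strata (benign,
   borderline, stage I–II, stage III–IV, metastasis). The per-stratum
   validation count is round-half-up of 0.30 × stratum size — the convention
   is a package choice; no rounding rule is canonical.

## Evaluation battery

* **AUC** by the rank/concordance identity (ties ½), CI by stratified
  percentile bootstrap, 2000 resamples, seeded. AUC ≡ U/(n₁n₀) is asserted
  as an exact identity in the tests.
* **DeLong** paired AUC comparison via midrank placements; the variance
  equals the grouped delete-one jackknife exactly (tested to 1e-10).
  Identical risk vectors return p = 1 by convention.
* **Classification at a cutoff**: positive iff risk ≥ cutoff (the ≥
  convention is a documented choice). Proportion CIs are normal
  approximation p ± 1.96√(p(1−p)/n); likelihood-ratio CIs use the log
  method. The 10% cutoff is the default clinical operating point; the
  Youden-optimal cutoff (max sens+spec−1 over observed risks, ties toward
  the *lowest* cutoff, i.e. the more sensitive point) is reported alongside.
* **Calibration**: slope from a logistic fit of outcome on logit(risk);
  intercept from a logistic fit with logit(risk) as fixed offset
  (intercept > 0 ⇒ risks systematically underestimated; slope < 1 ⇒ risks
  too extreme). The nonparametric curve is a local-linear (tricube kernel)
  smoother with bandwidth 0.3 of the observed risk range on a 50-point grid.
  Risks are clipped to [1e−6, 1−1e−6]; constant risks are an error.
* **Decision curves**: net benefit NB(t) = TP/n − FP/n · t/(1−t) on a
  1–50% threshold grid, with treat-all (π − (1−π)t/(1−t)) and treat-none
  (0) references.
* **Overfit_Score**: per feature, mean |SHAP| on the training split minus
  mean |SHAP| on the validation split, using exact TreeSHAP attributions
  computed by XGBoost (`pred_contribs`); attributions satisfy local
  additivity to the predicted log-odds. Because attributions of a *fixed*
  model depend on a split only through its feature distribution, the score
  detects features whose high-attribution (extreme) values were a
  training-split artifact and do not recur in validation — exactly the
  memorized-noise signature. It does not detect a feature whose validation
  values land in the same attributed regions; such transfer is not
  overfitting in this sense. The diagnostic requires a gradient-boosted
  model (exact attributions); random forests are rejected.
* **Manufacturer PCA**: PCA of the Z-scaled selected features, summarized
  as mean between-tag centroid distance over mean within-tag RMS spread in
  the first two components. Because per-ROI Z-scoring removes the
  generator's vendor gain/offset exactly, vendor clusters overlap.

## ADNEX comparator

The comparator is a multinomial-logistic risk calculator over nine
clinical/ultrasound predictors (age, oncology-center status, log₂ CA 125,
log₂ maximal lesion diameter, proportion of solid tissue, >10 locules,
papillary projections 0–4, acoustic shadows, ascites) with benign as the
reference class and four malignant classes; risk of malignancy is
1 − P(benign). Two variants exist, with and without CA 125; the
with-CA 125 variant is used whenever the marker is available. Coefficients
load from a human-readable JSON file. **The bundled file is a synthetic
stand-in**: it reproduces the published model's structure and coefficient
signs but not the published values (which are not redistributable here);
every shipped test of the calculator is structural (probability simplex,
per-predictor monotonicity, variant contract) and holds for any valid
coefficient file. For clinical use, transcribe the published coefficients
into a file of the same schema and pass it to `load_coefficients`.

## Synthetic cohort generator

The generator reproduces the *statistical structure* the analysis assumes,
not acoustic physics:

* **Class mix** defaults to 61.3% benign / 5.5% borderline / 12.9%
  stage I–II / 15.7% stage III–IV / 4.7% metastasis (38.7% malignant
  overall), matching the composition of the cohort the workflow targets.
* **Images** are a low-frequency echo field times gamma-distributed
  multiplicative speckle (shape 4, mean 1 — the fully-developed-speckle
  approximation), with a random elliptical hypoechoic lesion ROI (≥ 32
  pixels) in a 96×96 frame. Malignant strata receive extra low/high-
  intensity Gaussian blobs inside the ROI whose number, size and amplitude
  scale with a per-stratum weight (borderline 0.6 < metastasis 0.9 <
  stage I–II 0.85 < stage III–IV 1.0) times the `texture` effect size. The
  blobs were chosen specifically to raise intensity kurtosis and gray-level
  non-uniformity — the features this kind of model leans on.
* **Clinical covariates**: age is normal with a class-shifted mean (benign
  48 y; shifts up to +12 y for advanced disease); CA 125 is log-normal with
  class-shifted location (up to +2.4 log-units) and is masked missing
  completely at random at rate 0.25. A subjective-assessment column is
  drawn with sensitivity 0.96 / specificity 0.86 conditional on outcome.
* **Manufacturer**: a uniform vendor tag applied as a mild global
  gain/offset (0.9–1.1, ±6), removed exactly by per-ROI Z-scoring.
* **ADNEX predictors** (diameters, solid proportion, papillations, ascites,
  shadows) are sampled conditionally on the outcome stratum with
  deliberately strong effects, so a correct calculator separates classes
  well on this cohort by construction.
* One image per case; a single seeded RNG stream per cohort gives
  byte-identical regeneration.

**Calibrated design target.** The generator's default effect sizes were
fixed once by a calibration simulation (`scripts/calibrate_generator.py`):
with defaults, a tuned radiomics-only gradient-boosted model reaches a
validation AUC of 0.814 (mean over three seeds at n = 2000), frozen as
`DESIGN_TARGET_AUC`. The parameter-recovery test regenerates a 2000-case
cohort and requires the achieved AUC within ±0.05 of this target; adding
the clinical covariates must improve validation AUC in ≥ 8/10 seeds
(checked at n = 320 per seed with a reduced 6-draw search); a zero-effect
cohort must stay at AUC 0.5 ± 0.1.

**What passing does not show.** The images are not acoustically realistic
(no attenuation, shadowing, beam geometry, or operator variability), lesion
shape carries no information, and segmentation is exact by construction.
Passing demonstrates that the pipeline's machinery is correct and recovers
designed effects — not that the feature set or models would perform at any
particular level on clinical images.

## Problem sizes and runtimes

The test suite uses cohorts of 60–2000 cases and reduced hyperparameter
searches (3–8 draws) so the whole suite runs in a few minutes on one CPU;
the acceptance script runs the full workflow at the target cohort size
(n = 2073) with a 10-draw search in about a minute. The exhaustive texture
check covers all 512 two-level 3×3 grids and all 65 536 4×4 grids at the
matrix level, with full feature-level brute-force comparison on all 3×3
grids and a 2000-grid 4×4 subsample (features are pure functions of the
matrices).

## Known limitations

* The bundled ADNEX coefficients are synthetic (see above).
* The 74-feature registry is one defensible IBSI-style composition;
  other compositions (e.g. including NGTDM) exist.
* Exact numerical agreement with any particular extraction platform is out
  of scope: discretization counts, direction merging and edge conventions
  differ between platforms and are documented here instead.
* Missing CA 125 restricts the clinical–radiomics variant to tree models;
  no imputation path is provided by design.
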