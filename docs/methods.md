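# Methods

`refnoise` studies a single question: when the binary clinical reference
used to train a radiomics-style classifier is partially wrong, how do
feature selection and model performance degrade — both as measured against
the corrupted labels and as measured against the truth?

## The experiment

A cohort is a real-valued feature table (n samples x p features) with a
binary reference (1 = clinically significant). The pipeline:

1. **Stratified 7:3 split.** `round(0.7 n)` samples form the training set;
   each class contributes `round(0.7 n_class)` up to rounding, so train and
   hold-out prevalences differ from the cohort by at most one sample's
   worth. The hold-out set is never permuted and never used in training.
2. **Reference permutation (training set only).** At level `L`, exactly
   `k = round(L * n_train)` training labels are inverted, drawn uniformly
   without replacement, `floor(k/2)` from one class and `ceil(k/2)` from the
   other, with the odd flip going to the majority class. This keeps the
   class balance within `1/n` of the original. Levels run 0–50% in 5%
   steps (11 levels); each level is repeated 20 times with independent
   draws. When a class cannot supply its half of the quota (possible only
   under extreme imbalance), the excess is reassigned to the other class;
   the `1/n` balance guarantee then no longer holds and the provenance
   records make this visible.
3. **Feature selection** (per repetition, on the permuted training set):
   - `mannwhitney`: two-sided Mann-Whitney U per feature, midrank normal
     approximation with tie and continuity correction; keep p < 0.05,
     unadjusted. Constant features get p = 1.
   - `rfe`: recursive elimination under an L2-logistic ranker on z-scored
     features; batch `max(1, p // 50)` until twice the target remains, then
     one-by-one, down to `n_target` features.
   - `lasso`: L1-penalized logistic regression on z-scored features, the
     penalty chosen by stratified CV on the binomial deviance; keep
     features with nonzero coefficients.
   - `mrmr`: greedy forward selection maximizing mutual-information
     relevance minus mean redundancy (MID criterion), with plug-in MI on
     `ceil(sqrt(n))` equal-frequency bins; ties break toward the earlier
     feature column.

   Every selector guarantees a non-empty result: if nothing survives, all
   features are returned and flagged (`fallback_used`). The fallback is not
   cosmetic — with heavily corrupted labels sparse selectors legitimately
   retain nothing, and the all-features fallback makes the stability index
   jump to 1 when it fires in every repetition, a behaviour the experiment
   is designed to exhibit.
   `n_target` for RFE/mRMR defaults to `min(30, n_train // 5)`, capping
   model complexity relative to sample size.
4. **Classification** under stratified K-fold CV on the permuted labels
   (K = 10 when `n_train >= 150`, else 5; reduced to the minority-class
   count if necessary). Classifiers: random forest (500 trees, sqrt(p)
   features per split) and L1-logistic regression (penalty grid 10^-2..10^2,
   8 points, chosen by inner 3-fold stratified CV on log-loss; features
   z-scored with training-fold statistics). Scores are class-1
   probabilities.
5. **Three evaluation surfaces**, each yielding AUC (midrank), accuracy,
   sensitivity and specificity at a 0.5 cutoff:
   - `train_vs_permuted`: pooled out-of-fold scores vs the permuted labels;
   - `train_vs_true`: the same scores vs the true training labels;
   - `holdout_vs_true`: the final model (refit on the full permuted
     training set) vs the true hold-out labels.
6. **Statistics.** Selection stability per (selector, level) is the
   multi-set Jaccard similarity across the 20 repetitions' selected sets,
   `|intersection| / |union|` (1 when the union is empty). Metrics are
   compared across levels by one-way fixed-effects ANOVA with all-pairs
   Bonferroni-adjusted t-tests, significance at adjusted p < 0.05.

## Where the feature selection happens relative to CV

Stability (JSC) is defined over one selected set per repetition, so the
canonical selection runs once on the full permuted training set; that
selection also feeds the final model used for hold-out scoring. For the
*out-of-fold* training surfaces, however, re-using a selection computed on
the full training set would leak each held fold's labels into the features
its model sees: features spuriously correlated with the label noise are
chosen using the very fold being scored, and because a small fold
contributes disproportionately to extreme full-sample correlations, the
inflation is large. Measured on the balanced cohort profile, that variant
inflates mean out-of-fold AUC against permuted labels by about +0.14 at the
50% level (0.64 instead of the chance level 0.5) and breaks the expected
monotone decline. The default (`selection_in_cv=True`) therefore re-runs
the selector inside each training fold for out-of-fold scoring, which
restores the correct null endpoint (0.50 measured at level 0.5). The
single-selection variant remains available (`selection_in_cv=False`) for
comparison with studies that selected once per training set — its inflated
training surface is a faithful reproduction of that practice, not a bug.

## The noisy-AUC closed form

For a *fixed* scoring rule with true AUC `A`, evaluated against labels with
per-class flip counts `(k_pos, k_neg)`, each noisy class is a mixture of
true positives and true negatives. With mixture weights
`w_pp = (n_pos - k_pos) / (n_pos - k_pos + k_neg)` (truly-positive share of
the noisy-positive group), `w_pn = 1 - w_pp`, and `w_nn`, `w_np` likewise
for the noisy-negative group:

    AUC_noisy = w_pp * w_nn * A + w_pn * w_np * (1 - A)
                + (w_pp * w_np + w_pn * w_nn) / 2

assuming negligible score ties. This is the identity at level 0, exactly
0.5 at level 0.5 with balanced classes, and strictly decreasing in level
for A > 0.5. It is validated against a Monte-Carlo flip oracle in the
tests.

The closed form deliberately ignores that the *model itself* is retrained
on the noisy labels. Two real effects make the measured curve deviate from
it: (a) at moderate-to-high levels the trained model genuinely loses
discrimination (the per-class effective effect size scales as
`(1 - 2L) * d`, so at L = 0.45 a d = 1 signal shrinks to 0.1 — unrecoverable
at n = 182), pulling the measured curve *below* the closed form by up to
~0.1 around levels 0.2–0.4; and (b) any selection leakage pulls it above.
The closed form is therefore an upper envelope for a leakage-free pipeline,
tight at both ends of the level range, rather than a pointwise prediction
at mid levels.

## Synthetic cohorts

Two generator profiles mirror the public prostate-MRI radiomics cohorts
the experiment design targets:

| profile  | n   | p    | prevalence | informative | d   | CV folds |
|----------|-----|------|------------|-------------|-----|----------|
| dataset1 | 260 | 265  | 0.49       | 10          | 1.0 | 10       |
| dataset2 | 100 | 7106 | 0.80       | 20          | 1.0 | 5        |

Class-conditional features are equal-variance Gaussians. Informative
features are mutually independent, each shifted by `d * noise_sd` in the
positive class; a single such feature has closed-form AUC
`Phi(d / sqrt(2))`, the generator's calibration oracle. Non-informative
features are organized into equicorrelated blocks (size 5, rho = 0.8) built
from a shared latent factor, mimicking redundant radiomics feature families
and exercising the mRMR redundancy term; informative features are kept out
of the blocks because placing them inside rho = 0.8 blocks caps the
achievable AUC near 0.86, whereas the profiles are meant to operate in the
~0.94–0.97 regime observed for these cohorts. The positive count is exactly
`round(prevalence * n)` for every seed.

What the generator does *not* emulate: real radiomics feature
distributions (skewness, heavy tails, scale heterogeneity), correlation
between informative and noise features, and label noise that depends on the
features (e.g. borderline lesions being more error-prone). Passing tests
therefore demonstrate the machinery's correctness and the qualitative
degradation phenomenology, not quantitative transfer to any real cohort.

## Numerical and reproducibility choices

- All count computations (split sizes, flip quotas, positive counts) use
  round-half-away-from-zero, one documented rule to avoid platform drift.
- Every random quantity derives from one master seed through
  `numpy.random.SeedSequence` spawn keys `(purpose, level, selector,
  classifier, ...)`; any single cell of the factorial is reproducible in
  isolation, and repetitions at level 0 are bit-identical because the only
  repetition-specific randomness is the flip draw.
- Accuracy/sensitivity/specificity use a fixed 0.5 score cutoff
  (configurable).
- AUC uses midranks, consistent with the tie-corrected Mann-Whitney
  statistic; a degenerate all-tied score vector scores 0.5.
- mRMR's MID criterion is the difference form (relevance minus mean
  redundancy); the quotient form is not implemented.
- The mRMR/RFE target size, penalty grids and tree counts are documented
  defaults, configurable via `ExperimentConfig`.

## Problem sizes used in the shipped checks

The headline acceptance run uses the dataset1 profile with the
Mann-Whitney + L1-logistic pipeline (the cheapest of the eight, making the
11 x 20 factorial tractable on one CPU); selector-stability checks run
RFE/LASSO/mRMR at levels 0 and 5%; the variability comparison between the
two cohort shapes uses scaled-down analogues (p = 80 vs p = 300) with the
same contrast in n, dimensionality and prevalence. The full eight-pipeline
grid on both full profiles is available through `refnoise run` for users
with more patience.

## Known limitations

- The eight-pipeline grid is a pure cross-product; no interaction between
  selector and classifier hyperparameters is tuned.
- The ANOVA treats repetitions as independent replicates; repetitions share
  the same training cohort, so between-level tests are anti-conservative
  for cohort-level inference.
- Binary outcomes only; no multi-class or time-to-event references.
- The permutation model is symmetric and feature-independent by design.
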