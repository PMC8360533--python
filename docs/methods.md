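# Methods

## The question

A common design in small-sample classification studies — radiomics being
the motivating field — is to split the available cohort once into a
training and a test set, tune a model on the training part with internal
validation (cross-validation or bootstrap), and report the test-set AUC as
the validated performance. `splitgap` treats the split itself as the random
variable: it repeats the whole procedure over many split seeds and measures
the distribution of the internal estimate, the test AUC, and the
*optimism* (internal estimate minus test AUC, also reported with the
opposite sign as `printed_difference`).

## The model under audit

Each trial fits the same three-stage pipeline on the training part only:

1. **Standardization** — per-feature z-scoring with the training mean and
   sample SD (ddof = 1). Zero-variance training columns are mapped to 0
   (SD replaced by 1) so no division by zero occurs at small n.
2. **Feature selection** — two-group ANOVA F statistics,
   F = SSB / (SSW / (n − 2)), computed on the standardized features (the
   two-group F is invariant to per-feature affine maps, so raw-vs-scaled is
   immaterial). The top-k features are kept; ties break toward the lower
   column index; constant columns get F = 0 and a within-class-constant but
   separated column gets +inf, ranked above any finite score.
3. **Classification** — L1-penalized logistic regression (the LASSO in its
   classification form) with inverse regularization strength C, solved by
   liblinear (tol 1e-6, 10,000 iterations; non-convergence is flagged on
   the trial, not fatal). The mismatch demonstration instead fits a linear
   SVM on the top-2 features.

Hyperparameters (k, C) are tuned by stratified 5-fold grid-search CV on a
fold assignment shared across the grid; the winner maximizes the mean fold
AUC with ties broken toward smaller k, then smaller C. The winning mean CV
AUC is the trial's internal estimate. The default grid is
k ∈ {20, 25, 30, 35, 40, 45, 50, 55} × C ∈ {0.01, 0.03, 0.09, 0.3, 0.9,
1.5, 3, 8, 10}; the endpoints are the conventional sweep range for this
recipe and the interior is log-ish spaced.

## Resampling rules

* **Train-test split**: stratified, per class floor(n_c × fraction) rows to
  training, the remainder to test. The floor rule is frozen so counts are
  reproducible: 109/58 at 7:3 gives train (76, 40) and test (33, 18).
* **Undersampling**: floor(n_c × fraction) rows retained per class, once
  per arm with a dedicated arm seed; trials then re-split the reduced
  table.
* **Folds**: stratified k-fold (per-class fold sizes differ by ≤ 1),
  shuffled by seed. Unstratified folds can lose a class entirely around
  n ≈ 50, which is exactly the regime under study.
* **Bootstrap out-of-bag**: n draws with replacement, pipeline refit on the
  in-bag rows, AUC scored on the out-of-bag complement (fraction
  (1 − 1/n)^n ≈ e⁻¹ ≈ 0.368 at large n); draws missing a class on either
  side are redrawn, capped at 100 retries.
* **Seeds**: every operation is a pure function of (inputs, seed). Child
  streams are derived by hashing (master seed, purpose tag, index) through
  `numpy.random.SeedSequence`, so adding repetitions or reordering work
  never perturbs existing streams, and all derived seeds stay below 2^31.

Every estimator refits the *entire* pipeline (standardizer, selector,
classifier) inside each fold or draw. Scoring the held-out part with a
selector fit on all rows is the classic leakage that inflates internal
estimates; the leakage-guard tests assert the training side is blind to
test-row values.

## AUC and its confidence interval

The AUC is the Mann–Whitney statistic (ties weight ½), computed with
midranks — algebraically identical to exhaustive pair enumeration, which
the tests use as an oracle. Its variance is the DeLong U-statistic
estimate: with placements V10 (per positive, mean win rate over negatives)
and V01 (per negative), var = S10/m + S01/n with sample variances S.
Intervals are Wald, clipped to [0, 1] (a perfect-separation test set
legitimately prints an interval like 0.985–1.000). Sample SDs (n − 1)
are used throughout.

## The synthetic generator

The study's real-data analog is a brain-MRI radiomics table; the generator
reproduces its statistical hallmarks rather than its marginal
distributions: high dimension, a small informative subset, heavy
redundancy, and correlated nuisance features. Under class 0 all features
are unit-variance Gaussians:

* m informative features, independent, shifted by δ (standardized units)
  under class 1;
* redundant features, each a noisy copy (parent + ε)/√2 of a cycled
  informative parent — normalized so every column keeps unit variance
  (correlation 1/√2 with its parent, conveying no extra class
  information);
* the remaining nuisance features in equicorrelated blocks (default block
  size 10, pairwise correlation 0.3), independent of the signal.

Because the redundant copies are conditionally pure noise, the Mahalanobis
distance between class means is Δ = δ√m and the oracle (Bayes) AUC is
Φ(Δ/√2). `theoretical_auc` computes Δ from the assembled covariance rather
than this shortcut, and a simulation test confirms the two agree.
`calibrate_shift` inverts the map by Brent root-finding to 1e-9 in AUC, so
task difficulty is specified as a target oracle AUC: 0.95 for the "simple"
arm (class counts 109 vs. 58) and 0.78 for the "difficult" arm (163 vs.
95), bracketing the test performance reported for the corresponding real
tasks. Defaults: p = 400 features (the feature sweep goes to k = 150, so
the table must be comfortably wider), m = 10 informative, 30 redundant.

What the generator does *not* emulate: non-Gaussian marginals, the heavy
tail and skew of real radiomics features, feature-extraction artifacts,
scanner/batch effects, and label noise. Passing tests therefore show the
split-instability phenomenon is reproduced under a clean, favorable data
model — real tables can only be less stable, not more.

## Scaled study conditions

The repository's checks run a desk-scale version of the full design:
p = 200 features, 200 split trials per arm, grid k ∈ {20, 35, 50} ×
C ∈ {0.1, 1, 10}, four arms ({simple, difficult} × {full, 50%
undersampled}), master seed fixed at 0. At this scale the qualitative
conclusions are stable: SD(optimism) ordered simple_full <
difficult_under with undersampled arms above their full counterparts, mean
test AUC dropping under undersampling, and both strongly optimistic and
strongly pessimistic single splits (|gap| ≥ 0.1) occurring within 200
trials of the difficult arm.

## Validation-method comparison

For the optimistic trials (internal estimate > test AUC) of an arm, the
n_select largest-optimism trials form the *severe* group and the n_select
trials nearest the median optimism form the *moderate* group. Four
estimators re-estimate each selected trial's training performance:

* **cv** — the grid-search 5-fold CV estimate, reusing the trial's own
  fold seed, so it reproduces the estimate the trial reported (selection
  optimism included);
* **repeated_cv** — 10 fresh fold shuffles of the tuned configuration, all
  fold AUCs pooled;
* **nested_cv** — 5 outer folds, each tuning the full grid on its own
  training portion (pricing in the tuning itself);
* **bootstrap** — 10 out-of-bag draws of the tuned configuration.

Tuning happens once per trial; repeated CV and bootstrap evaluate that
fixed configuration, nested CV retunes internally. The reported per-method
test AUC is the trial's deployed-model test AUC. Expected ordering of mean
training estimates — bootstrap ≤ nested CV ≤ plain CV — follows from their
biases: out-of-bag training sets contain only ≈ 63% unique samples
(pessimistic), nested CV removes selection optimism, and plain CV keeps
it. In the severe group the residual gap stays positive for all four: no
internal estimator can detect that a particular split produced
distributionally mismatched halves.

## Feature-count sweep

Per split seed and per k (C fixed at 1.0, a conventional default), the
pipeline records the 5-fold CV estimate and the test AUC. The percentage
gap curve is 100 × (estimate − test)/estimate, averaged over seeds with a
normal-approximation 95% CI. Per fold, standardization and F-ranking are
computed once and reused across k — exactly equivalent to refitting per k,
since the ranking does not depend on k.

## Numerical and degenerate-input choices

* AUC ties contribute ½; all-tied scores give AUC 0.5 — which is also what
  a fully-penalized (C → 0⁺) classifier with zero coefficients earns.
* Single-trial summaries report SD 0 with an explicit `sd_defined=False`
  flag.
* Arm runs tolerate up to 5% individual trial failures (logged with their
  seeds) before failing the arm.
* The liblinear L1 path is not theoretically monotone in the active-set
  count; tests allow rare optimizer-tolerance violations.

## Known limitations

* The generator's equal-covariance Gaussian model makes the Bayes
  discriminant linear — kind to the linear pipeline under audit; nonlinear
  tasks would widen the gaps further.
* The bootstrap estimator is the plain out-of-bag average; .632/.632+
  corrections are deliberately out of scope.
* The mean-distance utility reports the Monte-Carlo mean pairwise distance
  in [0,1]^d: 1/3 (exact) in 1-D, ≈ 0.52 in 2-D, ≈ 0.66 in 3-D, ≈ 1.27 in
  10-D. A sometimes-quoted 10-D value of 3.16 is the cube *diagonal* √10,
  not the mean pairwise distance, and is not reproduced here.
* DeLong Wald intervals slightly undercover near AUC → 1 at very small n;
  the coverage test pins behavior at AUC 0.8, m = n = 50.
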