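# Methods

## The selection procedure

`profwise` addresses a recurring problem in serum/tissue proteomics: from a
panel of several thousand protein markers measured on a small cohort
(n ≈ 65–110), find the smallest feature subset that predicts a clinical
variable — a binary molecular status (e.g. MGMT promoter methylation,
methylated vs unmethylated) or a continuous protein expression level —
without committing to a single feature-selection heuristic.

The procedure combines one filter method and one embedded method inside a
fixed cross-validation plan:

1. **Fold plan.** Stratified 5-fold CV for binary targets (per-fold class
   counts within one sample of the proportional share); plain shuffled
   5-fold CV for continuous targets, unless a companion status label is
   supplied to stratify on. The plan is deterministic given the seed
   (default 0).

2. **Per-fold selection.** On each fold's training rows:
   * **mRMR** greedily ranks `n_select` features by
     `I(Y, X_i) − (1/|S|) Σ_{X_s∈S} I(X_s, X_i)`,
     where `S` is the already-selected set. The default estimator is
     plug-in mutual information after equal-frequency discretization into
     10 bins (binary targets used as-is); an F-statistic/|Pearson|
     variant is available as a faster alternative. Score ties within
     1e-9 break by ascending feature ID, making the ranking fully
     deterministic.
   * **LASSO** fits an L1-penalized model on the internally standardized
     training block and keeps features with |coefficient| > 1e-10.
     Binary tasks use L1-penalized logistic regression with C = 1/penalty
     (default penalty 1.0); continuous tasks use the linear objective
     `argmin_β ‖y − Xβ‖²/(2n) + λ‖β‖₁` on standardized X **and** y
     (default λ = 0.1, i.e. on the correlation scale: features whose
     marginal correlation with the target is below ≈0.1 cannot enter).

3. **Rank-based weighting.** Each feature's selections are summed across
   folds, weighted by the selector that picked it:
   `weight(f) = Σ_folds [w_lasso·1(f∈lasso) + w_mrmr·1(f∈mrmr)]`.
   Both assignments {w_lasso, w_mrmr} = {1,2} and {2,1} are evaluated —
   weight 2 encodes "this selector is ranked more effective". With 5
   folds the maximum weight is 5·(1+2) = 15.

4. **Threshold sweep.** For every minimum weight k = 1 … max observed
   weight, the candidate subset {f : weight(f) ≥ k} (these are nested) is
   scored by cross-validated mean accuracy (classification: SVM, logistic
   regression, KNN, random forest, AdaBoost) or mean squared error
   (regression: SVR, random forest), using the same fold plan.

5. **Winner.** The cell with the best score wins; ties prefer fewer
   features, then smaller k, then the fixed model order, then the weight
   assignment order. This "best score with minimum features" rule is the
   method's defining trade-off.

## Evaluation protocol and its bias

By default the *same* fold plan drives selection and evaluation. This
reproduces the single-CV protocol the method was designed around but is
optimistically biased: each fold's test rows participated in the other
folds' selection. `nested_evaluation=True` re-splits evaluation folds from
an independent seed stream for bias-controlled estimates. Sweep tables
from the default mode should be read as *relative* comparisons between
thresholds, not unbiased generalization estimates.

Models are fixed (no tuning): SVM C=1/RBF/gamma-scaling, LR L2 C=1.0, KNN
k=5 Minkowski uniform, RF 100 trees Gini, AdaBoost 50 estimators lr=1.0,
SVR and RF-regressor at library defaults; every stochastic component is
seeded with 0. scikit-learn ≥1.6 removed AdaBoost's `SAMME.R` switch; the
current (real-valued) boosting implementation is used. Features handed to
a model are standardized on the training fold only (fit on train,
transform test) to avoid scaling leakage.

## Preprocessing regimes

* `log2_rfu` — positive aptamer-panel intensities (RFU) are log2-
  transformed; non-positive values are a hard error.
* `zscore` — already-normalized matrices are z-scored per feature
  (sample sd, ddof=1); constant features are dropped with a warning.
* Missing or non-numeric cells are hard errors with coordinates. No
  imputation is performed — silently imputed values would change
  selections invisibly.
* For regression on a marker's own expression, that marker is removed
  from the predictor set (`exclude_target_feature`), e.g. a 7289-marker
  panel yields 7288 predictors.

## The synthetic testbed

`profwise.synthetic.generate` emulates the *structure* of the target data:

| parameter | default | meaning |
|---|---|---|
| n_samples | 100 | cohort size |
| n_features | 1000 | panel width (desk-scale; real panels are 7–9k) |
| n_informative | 10 | truly predictive markers |
| n_redundant_per_informative | 2 | correlated aptamer-like copies per marker |
| redundancy_rho | 0.8 | copy–parent correlation |
| effect_size | 1.5 | between-class mean shift (classification) or per-feature slope (regression), in noise-sd units |
| class_ratio | 27/65 | positive fraction (mild imbalance) |
| noise_sd | 1.0 | sd of noise features / regression noise |
| unknown_fraction | 0.0 | labels masked as "unknown" |

Copies are `rho·x + sqrt(1−rho²)·ε`, so they share the parent's gene
symbol and carry an attenuated copy of its signal — this exercises mRMR's
redundancy penalty and symbol-level reporting. The generator does **not**
model proteome-wide covariance, batch effects, heteroscedastic assay
noise, or plate structure; passing tests demonstrate the machinery's
correctness on clean planted signal, not performance on real serum data.
Dimensions were chosen so a full pipeline run takes well under a minute
on one CPU; they deliberately do not mimic a full 7k panel.

## Numerical choices

* MI is plug-in (no bias correction) on equal-frequency bins; quantile
  edge ties are collapsed, so low-cardinality features get fewer bins.
* Greedy mRMR ties (scores within 1e-9 of the step maximum) break by
  ascending feature ID; the same rule is applied by the brute-force
  oracle in the test suite.
* LASSO: zero-variance columns can never be selected; solver
  non-convergence downgrades to a warning and returns the current
  nonzero set.
* `%.17g` formatting plus numpy's correctly-rounding parser make matrix
  write→read round-trips bit-identical.
* Empty threshold subsets are recorded with size 0, never scored, and
  never win.

## Known limitations

* **Score saturation.** When the task is easy (strong planted effects,
  or heavily selection-biased evaluation), mean CV accuracy saturates at
  1.0 across many thresholds; the minimum-feature tie rule then selects
  a very small subset that need not cover every informative group, even
  though the k=1 union does. On the default synthetic scenario the
  winner covers 6 of 10 planted groups with 6 features at perfect
  accuracy, while thresholds k ≤ 9 cover all 10. Users who want coverage
  rather than parsimony should inspect the full sweep table, which the
  report always contains.
* The per-fold mRMR budget `n_select` (default 50) and the LASSO penalty
  are protocol constants, not tuned values; selection results depend on
  them and they are recorded in every run manifest.
* With ≤ 3 distinct non-unknown string levels the target loader assumes
  a binary label; numeric-looking binary encodings (0/1) are read as
  continuous unless the column is quoted as text.
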