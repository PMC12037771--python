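# Methods

## Problem and scope

`vttml` re-implements, as a reusable pipeline, the translational analysis of
a small single-arm neoadjuvant trial of a VEGFR-directed tyrosine kinase
inhibitor in clear cell renal cell carcinoma with venous tumour thrombus
(VTT). The pipeline covers five stages: (1) response evaluation from
MRI-measured thrombus lengths, (2) pre-processing of a patients × features
table, (3) a leave-one-out cross-validated feature-selecting classifier
with consensus importance, (4) classification metrics over the pooled
out-of-fold scores, and (5) transcriptomic signature scoring with quartile
survival stratification. Because the trial's measurement table is not
distributed here, a first-class synthetic cohort generator emulates its
statistical structure so that every stage can be exercised and tested end
to end.

## Response evaluation

Total VTT length is the sum of three segments (renal-vein thrombus, IVC
thrombus above and below the renal vein ostium), in millimetres. Response
is the percent change at week 9 versus baseline, (L_T − L_B)/L_B × 100. A
patient is a responder iff the percent change is strictly below −30 ("more
than 30% reduction"); a change of exactly −30.0% is a non-responder. The
threshold is configurable. Patients missing the baseline or week-9 scan are
excluded with a logged warning. Extreme follow-up values (growth beyond
+100%, shrinkage to zero length) are treated as ordinary values of the
formula.

## Pre-processing

Three steps, applied in order:

1. **Iterative imputation.** Chained-equation imputation: each incomplete
   feature is regressed on all others with a Bayesian ridge (penalty
   inferred from the data), cycling until the largest change is below `tol`
   or `max_iter` rounds (defaults `tol = 1e-3` on the scaled scale,
   `max_iter = 10`; these were unconstrained choices). Observed cells are
   preserved exactly. A fully missing row or column is an error.
2. **Min-max scaling.** Each feature is mapped to [0, 1] by
   (x − min)/(max − min). A constant feature maps to all zeros. Scaling
   parameters are retained so held-out rows can be transformed with
   training statistics; out-of-range held-out values extrapolate rather
   than clip.
3. **Collinearity pruning.** All pairwise Spearman rank correlations
   (average ranks on ties) are computed; features joined by |ρ| strictly
   above 0.75 form a graph, and each connected component — the natural
   formalisation of a "collinear group" — keeps exactly one member chosen
   uniformly by a seeded RNG. Absolute ρ is used so strong negative
   correlations also count as redundancy; this and the threshold are
   configurable. A correlation equal to the threshold up to floating-point
   rank arithmetic (guard 1e-12) is retained. Pruning a pruned table drops
   nothing.

Two modes exist. The default reproduction mode applies the three steps once
to the full table before cross-validation, matching the original analysis
order. A leakage-safe mode (`preprocess_mode="per_fold"`) refits imputation
regressions, scaling ranges and prune decisions on each training subset and
applies them to the held-out patient; it is slower and not the default, but
is the mode to prefer for honest generalisation estimates on new data.

Week-3 dynamic features are per-patient fold changes, value(week 3) /
value(week 1), of the longitudinal plasma markers; a missing or zero
baseline yields a missing entry that is imputed downstream. The dynamic
model is the column-concatenation of the 62 baseline features and the 7
fold-change features (69 columns).

## Prediction framework

For each left-out patient (20 iterations at n = 20):

1. **Inner grid search.** Stratified 5-fold cross-validation on the
   remaining 19 patients tunes the hyperparameters of an SGD-fitted
   logistic regression, maximising mean inner-fold ROC AUC; ties go to the
   first grid point in declaration order. If the minority class is smaller
   than 5, the fold count shrinks to it with a warning. The default grid —
   regularisation strength α ∈ {1e-4 … 1}, penalty ∈ {L2,
   elastic-net(l1_ratio = 0.15)}, learning schedule ∈ {optimal,
   adaptive(η₀ = 0.01)} — is a package default and fully overridable; any
   externally documented grid can be transcribed into the config.
2. **Recursive feature elimination.** With the tuned hyperparameters, the
   estimator is refitted repeatedly, removing the single feature with the
   smallest |coefficient| per round until `n_features_rfe` (default 3)
   remain. One-per-round elimination is the strict reading of "recursive";
   ties take the first minimum.
3. **Refit and score.** The model is refitted on the reduced training set
   and the held-out patient receives a predicted response probability via
   the logistic link.

The pooled out-of-fold scores over all iterations yield one ROC; this
pooled AUC is the reported cross-validated AUC. Threshold metrics use a
strict positive call at score > 0.5.

**Consensus importance.** Selection frequency = iterations in which a
feature survived RFE / total iterations. Relative weight within one
iteration = |coef| / Σ|coef| over that iteration's selected set; the mean
is taken over the iterations in which the feature was selected. Features at
frequency ≥ 0.4 (≥ 8 of 20 iterations) are flagged as the consensus set.

**Seeding.** Each LOOCV iteration derives its seed from the master seed and
the left-out patient id (CRC32 mix), so an iteration's randomness does not
depend on cohort ordering or size, and perturbing the held-out patient's
features cannot change the model fitted for that iteration. A seed-ensemble
helper reruns both models across K master seeds on the same data and
reports metric means, since fold shuffling, SGD ordering and prune
tie-breaks are the only stochastic elements once the data are fixed.

## Metrics

ROC AUC is the Mann–Whitney concordance probability (ties credited 0.5),
computed by scikit-learn and property-tested against a brute-force O(n²)
pairwise oracle. PR AUC uses the average-precision (step-integral) form,
not trapezoidal interpolation — the two differ slightly and the choice is
flagged. Threshold metrics are the standard confusion-matrix quantities at
score > threshold.

## Signatures and survival

Genes enter the expression analysis if the maximum count per biopsy is
strictly greater than 10 and strictly more than 50% of biopsies have
nonzero counts. Response / non-response signatures are the genes with
padj < 0.05 and log2 fold change > 2 (respectively < −2), all strict.
The signature score of a patient is the mean over signature genes of
(expression − gene mean)/gene SD across patients, with the sample (n−1)
SD; genes absent from the matrix or with zero variance are dropped with a
warning. Variance stabilisation of counts is upstream of this module: it
consumes an already-normalised matrix, and the synthetic generator emits
log-scale values directly.

Quartiles are linear-interpolation sample quantiles with inclusive
boundaries: the hi stratum is {response score ≥ Q3} ∩ {non-response score
≤ Q1}, the lo stratum the mirror set. Kaplan–Meier medians (earliest time
with survival ≤ 0.5; undefined if never reached) and the two-group
log-rank test are computed with lifelines; the log-rank path is verified in
the tests against an independent hand-rolled O/E/V implementation. Six
published renal-cancer signatures (two external-trial Angio/Immuno pairs
and the trial's own Angio/Immuno lists) plus the two pseudo-signatures used
for external stratification ship as a versioned JSON registry with gene
symbols transcribed as printed in their sources.

## Synthetic cohort generator

All randomness flows from one seed through named `SeedSequence` substreams
(labels, features, VTT, plasma, expression, survival), so a fixed seed is
bit-reproducible and adding a block never perturbs earlier blocks. Defaults
are the study conditions: 20 patients, 7 responders, 62 baseline features,
5% missingness (missing at random, never in labels or VTT lengths).

* **Baseline features** are unit-variance Gaussians on a latent scale
  (downstream scaling to [0,1] makes the marginal family immaterial).
  Discriminative features receive a responder-group location shift in SD
  units. Default shifts follow the reported univariate group comparisons:
  CCL17 −2.2 (near-complete separation in the scaled view), CD31/CD34
  microvessel density +2.0 with the mono-stain read-outs at +1.4,
  IL-12p70 −1.3, VEGF-C −1.0, IL-7 −0.6, circulating CD8% −0.5. A
  configurable set of latent shared factors creates realistic redundancy
  (two flow-cytometry pairs above the 0.75 pruning threshold, a weaker
  shared vessel factor across the three MVD read-outs). Inter-feature
  correlation beyond this is not modelled — an acknowledged simplification.
* **VTT trajectories** draw the week-9 percent change from truncated
  normals (responders strictly below −30%, non-responders at or above),
  with responder mean −50%, non-responder mean −10%, SD 12; week 3 shows
  ~45% of the final change. Segment lengths (baseline total lognormal
  around 90 mm, Dirichlet split) shrink proportionally. By construction the
  stored label always equals the label recomputed from the trajectory.
* **Plasma markers** follow level = baseline × multiplier^profile(week) ×
  lognormal noise (σ = 0.3), where the multiplier is the group's
  geometric-mean week-3 fold change and the profile relaxes toward baseline
  by week 9. Defaults: PlGF 7.0 vs 1.3 (the dominant dynamic signal),
  sVEGFR1 1.5 vs 1.1, VEGF-A 1.4 vs 1.1 (its induction peaks late, so the
  week-3 contrast is modest), sTie-2 0.65 vs 0.95, others null.
* **Expression** is negative-binomial (dispersion 0.2, a typical bulk
  RNA-seq scale) with 40 planted genes at |log2FC| = 3 (half up, half
  down in responders).
* **Survival** is exponential with configurable hazard ratio (default 4)
  between groups, low-hazard median 12 months, and independent exponential
  censoring (default 0.02/month).

What the generator does **not** emulate: real covariance among the 62
features, non-Gaussian marginals, informative missingness, measurement
batch effects, library-size variation in counts, or non-proportional
hazards. Tests passing on synthetic cohorts therefore demonstrate the
pipeline's correctness and calibration, not clinical validity on real
trial data.

## Problem sizes used in the checks

The acceptance-style checks use: a 25-seed ensemble of both models on one
fixed 20-patient cohort; a 5-seed (tests) / 3-seed (script) RFE-size sweep
over k = 1..10; 50 (tests) / 20 (script) null cohorts at 20 features with a
single-point grid — the null calibration does not depend on the grid — and
20 planted-signal cohorts with a reduced four-point grid; 500 null log-rank
simulations at 100 patients per arm (at 25/arm the χ²₁ reference is
measurably anti-conservative, true rate ≈ 0.066, an established
finite-sample property of the test rather than an implementation issue);
and 100 survival-power replicates at strata of 47 vs 28.

## Known limitations

* The reproduction (global) preprocessing mode leaks ranking information
  across CV folds by design fidelity; the per-fold mode exists for honest
  estimates but is not what the reported numbers use.
* Published point metrics were produced on the original trial's dataset;
  on a synthetic stand-in cohort the operating point differs, and
  point-value agreement should not be over-interpreted in either
  direction.
* Pooled-score LOOCV has a structural fragility at this sample size: the
  inner 5-fold AUC is estimated on validation folds of ~4 patients, so the
  selected hyperparameters vary across iterations, and iterations that
  land on strong regularisation emit nearly flat probabilities. Pooling
  probabilities across differently calibrated per-iteration models can
  then collapse the pooled ROC on some cohort draws even when feature
  selection is stable and correctly signed — observed on synthetic draws
  where CCL17 is selected in ~99% of iterations yet pooled baseline AUC
  sits near chance, while other draws of the same generator give ~0.8.
  The same fragility makes the AUC-vs-k sweep noisy. Consensus selection
  frequency is far more stable than the pooled metrics and is the output
  to trust at n = 20.
* With ~20 patients, pooled-AUC differences of ±0.05 correspond to roughly
  one discordant patient pair; the seed ensemble quantifies algorithmic
  variance only, not sampling variance.
* The log-rank and KM routines assume right-censoring independent of the
  event process.
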