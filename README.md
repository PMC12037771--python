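# vttml

Predictive biomarker modelling of venous tumour thrombus (VTT) response to
neoadjuvant anti-angiogenic therapy in clear cell renal cell carcinoma.

In 10–15% of renal cancers the primary tumour grows into the renal vein and
inferior vena cava as a venous tumour thrombus. Shrinking the thrombus with
a VEGFR-directed tyrosine kinase inhibitor before surgery can make the
operation less invasive, but only a minority of patients respond, and the
trials are necessarily small. `vttml` implements the translational analysis
pipeline for this setting: it classifies responders from MRI thrombus
lengths, pre-processes a small patients × features table of blood, tissue
and clinical markers, trains a leave-one-out cross-validated
feature-selecting classifier to predict response, aggregates a consensus
feature importance, and scores transcriptomic signatures with quartile
survival stratification. A synthetic cohort generator reproduces the
statistical structure of such a trial so the whole pipeline is runnable and
testable without access to patient data.

## The model at the core

* **Response**: a patient is a responder iff the total VTT length
  L = L_RV + L_IVC↑ + L_IVC↓ changes by (L_T − L_B)/L_B × 100 < −30 at
  week 9.
* **Pre-processing**: iterative (Bayesian-ridge chained-equation)
  imputation → min-max scaling to [0,1] → collinearity pruning that keeps
  one random member of each group of features with pairwise Spearman
  |ρ| > 0.75.
* **Prediction**: for each left-out patient i of n, an inner stratified
  5-fold grid search tunes an SGD-fitted logistic regression by ROC AUC on
  the remaining n−1; recursive feature elimination (dropping the smallest
  |coefficient| one feature per round) reduces to k = 3 features; the
  refitted model scores patient i. The pooled out-of-fold scores give the
  cross-validated ROC, and the fraction of iterations in which each
  feature survives RFE is its selection frequency (consensus importance).
  A "dynamic" variant appends week-3/baseline fold changes of 7 plasma
  angiogenic markers (62 → 69 features).
* **Signatures**: gene score z_gp = (x_gp − mean_g)/sd_g; patient score =
  mean over signature genes. Response/non-response signatures are genes
  with padj < 0.05 and log2FC > 2 (< −2). Patients in the top response
  quartile and bottom non-response quartile form the "hi" stratum (the
  mirror set "lo"); progression-free survival is compared by Kaplan–Meier
  medians and the log-rank test.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_classify_response.py
```

prints (abridged):

```
cohort: 20 patients x 62 baseline features
responders (VTT shrinkage > 30% at week 9): 7/20
missing feature cells: 4.4%
...
P01                 -34.5       True
P02                 -26.4      False
...
7/20 responders -> results/labels.csv
```

P01's thrombus shrank 34.5% by week 9 (more than 30%, so a responder);
P02's 26.4% shrinkage falls short. Then

```bash
python analysis/03_preprocess_features.py
python analysis/04_train_models.py
```

imputes the 54 missing cells, scales, prunes the collinear features
(e.g. `pruned 'CD8 %' (|rho|=0.91 with retained 'CD8 effector %')`), and
runs both models, printing the consensus importance and the side-by-side
table:

```
baseline model: 62 features in, pooled AUC 0.473
feature                     times_selected  selection_frequency  ...
CCL17                                   19                 0.95
IL-12p70                                18                 0.90
CD4/FoxP3 density (tissue)              13                 0.65

dynamic model: 69 features in, pooled AUC 1.000
PlGF FC w3                20                 1.00
sTie-2 FC w3              16                 0.80
CCL17                     13                 0.65

| Metric | Baseline model | | Dynamic model |
| AUC ROC | 0.473 | < | 1.000 |
| Specificity | 1.000 | = | 1.000 |
```

The dynamic model — dominated by the ~7-fold week-3 PlGF induction in
responders — separates the classes perfectly on this draw. The baseline
model's feature selection is stable and correctly signed (CCL17 and
IL-12p70 in 90–95% of leave-one-out iterations), yet its *pooled* AUC sits
near chance here: at n = 20 the inner hyperparameter search is noisy, and
pooling probabilities across differently calibrated per-iteration models
is fragile (other draws of the same generator give ~0.8; see
`docs/methods.md`, Known limitations). The consensus frequencies are the
stable output at this sample size. `analysis/05_sweep_features.py` traces
the pooled-AUC-vs-k curve used to choose the RFE size (noisy for the same
reason), and
`analysis/06_signatures_survival.py` builds the response/non-response gene
signatures on a larger synthetic cohort, stratifies it into hi/lo quartile
strata and prints their Kaplan–Meier median survival and log-rank p-value.

The same stages are available as a CLI (`vttml simulate|classify|
preprocess|train-loocv|sweep|report|score-signatures|stratify|run-all`).

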