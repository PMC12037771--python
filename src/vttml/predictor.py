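"""Leave-one-out cross-validated response prediction with consensus importance.

For each patient in turn, the remaining n-1 patients form a training set on
which an inner stratified 5-fold grid search tunes an SGD-fitted logistic
regression (optimising ROC AUC), recursive feature elimination (RFE) with
the tuned estimator reduces the feature set to ``n_features_rfe``, the model
is refitted on the reduced training set, and the held-out patient receives a
predicted response probability. Pooling the n out-of-fold scores yields the
cross-validated ROC, and aggregating the per-iteration RFE selections
yields a consensus feature importance: the selection frequency (fraction of
iterations in which a feature survived RFE) and the mean relative weight
(|coefficient| normalised within each iteration, averaged over the
iterations in which the feature was selected).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold

from . import metrics as _metrics
from .containers import FeatureTable
from .exceptions import ConfigurationError, ValidationError
from .preprocess import PreprocessModel

logger = logging.getLogger(__name__)


def default_grid() -> list[dict]:
    """Default hyperparameter grid for the SGD logistic estimator.

    Regularisation strength x penalty form x learning-rate schedule; fully
    overridable via :class:`PipelineConfig`.
    """
    grid = []
    for alpha in (1e-4, 1e-3, 1e-2, 1e-1, 1.0):
        for penalty in ({"penalty": "l2"},
                        {"penalty": "elasticnet", "l1_ratio": 0.15}):
            for sched in ({"learning_rate": "optimal"},
                          {"learning_rate": "adaptive", "eta0": 0.01}):
                grid.append({"alpha": alpha, **penalty, **sched})
    return grid


@dataclass
class PipelineConfig:
    """Configuration of the LOOCV prediction framework."""

    n_features_rfe: int = 3
    inner_folds: int = 5
    grid: list[dict] = field(default_factory=default_grid)
    scoring: str = "roc_auc"
    decision_threshold: float = 0.5
    seed: int = 0
    preprocess_mode: str = "global"   # "global" (reproduction) | "per_fold"

    def __post_init__(self) -> None:
        if self.n_features_rfe < 1:
            raise ConfigurationError("n_features_rfe must be >= 1")
        if self.inner_folds < 2:
            raise ConfigurationError("inner_folds must be >= 2")
        if not self.grid:
            raise ConfigurationError("hyperparameter grid is empty")
        if self.preprocess_mode not in ("global", "per_fold"):
            raise ConfigurationError("preprocess_mode must be global|per_fold")


@dataclass
class LOOIteration:
    left_out_id: str
    selected_features: list[str]
    weights: dict[str, float]
    best_hyperparams: dict
    oof_score: float


@dataclass
class LOOResult:
    iterations: list[LOOIteration]
    patient_ids: list[str]
    labels: np.ndarray
    config: PipelineConfig
    feature_names: list[str]

    @property
    def scores(self) -> np.ndarray:
        return np.array([it.oof_score for it in self.iterations])

    def metrics(self) -> dict:
        return _metrics.metrics_block(self.scores, self.labels,
                                      self.config.decision_threshold)

    def pooled_auc(self) -> float:
        return _metrics.roc_auc(self.scores, self.labels)


def make_estimator(params: dict, seed: int) -> SGDClassifier:
    return SGDClassifier(loss="log_loss", max_iter=1000, tol=1e-3,
                         random_state=int(seed), **params)


def _check_xy(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValidationError("X must be 2-D with at least one feature")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in X")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present in y")


def fit_classifier(X: np.ndarray, y: np.ndarray, params: dict,
                   seed: int) -> SGDClassifier:
    """Fit the SGD logistic model; seeded shuffling makes it reproducible."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_xy(X, y)
    est = make_estimator(params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def rfe_select(X: np.ndarray, y: np.ndarray, k: int, params: dict,
               seed: int) -> list[int]:
    """Recursive feature elimination, one feature per round.

    Repeatedly fits the logistic estimator and removes the feature with the
    smallest absolute coefficient until ``k`` remain. Returns the surviving
    column indices in their original order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_xy(X, y)
    p = X.shape[1]
    if not 1 <= k <= p:
        raise ValidationError(f"k must be in [1, {p}], got {k}")
    remaining = list(range(p))
    while len(remaining) > k:
        est = fit_classifier(X[:, remaining], y, params, seed)
        coefs = np.abs(est.coef_.ravel())
        remaining.pop(int(np.argmin(coefs)))   # first minimum on ties
    return remaining


def inner_grid_search(X: np.ndarray, y: np.ndarray, config: PipelineConfig,
                      seed: int) -> tuple[dict, float]:
    """Stratified k-fold grid search maximising mean inner-fold ROC AUC.

    Ties are broken by grid order (first maximum wins). Folds whose
    validation part lacks a class are skipped with a warning; if every fold
    is degenerate for the whole grid the search fails.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_xy(X, y)
    if not config.grid:
        raise ConfigurationError("hyperparameter grid is empty")
    n_splits = min(config.inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValidationError(
            "too few patients in the minority class for inner CV")
    if n_splits < config.inner_folds:
        logger.warning("inner folds reduced to %d (minority class size)", n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(seed))
    splits = list(skf.split(X, y))

    best_params, best_score = None, -np.inf
    for params in config.grid:
        fold_scores = []
        for f, (tr, va) in enumerate(splits):
            if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                logger.warning("degenerate inner fold %d skipped", f)
                continue
            est = fit_classifier(X[tr], y[tr], params, seed + f)
            scores = est.predict_proba(X[va])[:, 1]
            fold_scores.append(_metrics.roc_auc(scores, y[va]))
        if not fold_scores:
            raise ValidationError("all inner folds degenerate; cannot tune")
        mean_score = float(np.mean(fold_scores))
        if mean_score > best_score:
            best_params, best_score = params, mean_score
    return best_params, best_score


def loocv_run(table: FeatureTable, labels: pd.Series,
              config: PipelineConfig) -> LOOResult:
    """Leave-one-out cross-validation of the full selection + fitting chain.

    ``table`` must already be preprocessed when ``config.preprocess_mode`` is
    "global" (the reproduction mode); in "per_fold" mode imputation, scaling
    and pruning are refitted on each training subset and applied to the
    held-out patient, preventing information leakage.
    """
    labels = labels.reindex(table.patient_ids).astype(int)
    if labels.isna().any():
        raise ValidationError("labels missing for some patients")
    y_all = labels.to_numpy()
    n = table.n_patients
    if n < 3:
        raise ValidationError("need at least 3 patients for LOOCV")
    if len(np.unique(y_all)) < 2:
        raise ValidationError("both classes must be present")

    iterations: list[LOOIteration] = []
    for i, pid in enumerate(table.patient_ids):
        # per-patient substream: an iteration's randomness depends only on
        # the master seed and the left-out id, not on cohort size or order
        seed_i = int((zlib.crc32(str(pid).encode()) ^ (config.seed * 2654435761)) % 2**31)
        train_ids = [p for p in table.patient_ids if p != pid]
        try:
            if config.preprocess_mode == "per_fold":
                prep = PreprocessModel(seed=seed_i)
                train_tab = prep.fit_transform(table.select_patients(train_ids))
                test_tab = prep.transform(table.select_patients([pid]))
            else:
                train_tab = table.select_patients(train_ids)
                test_tab = table.select_patients([pid])
            Xtr = train_tab.to_numpy()
            ytr = y_all[np.arange(n) != i]
            feat_names = list(train_tab.feature_names)

            best_params, _ = inner_grid_search(Xtr, ytr, config, seed_i)
            sel_idx = rfe_select(Xtr, ytr, min(config.n_features_rfe, Xtr.shape[1]),
                                 best_params, seed_i)
            selected = [feat_names[j] for j in sel_idx]
            model = fit_classifier(Xtr[:, sel_idx], ytr, best_params, seed_i)
            xte = test_tab.values[selected].to_numpy(dtype=float)
            oof = float(model.predict_proba(xte)[0, 1])
        except ValidationError as exc:
            raise ValidationError(f"LOOCV iteration for patient {pid}: {exc}") from exc

        weights = dict(zip(selected, model.coef_.ravel().tolist()))
        iterations.append(LOOIteration(pid, selected, weights, best_params, oof))

    return LOOResult(iterations=iterations, patient_ids=list(table.patient_ids),
                     labels=y_all, config=config,
                     feature_names=list(table.feature_names))


def importance_summary(result: LOOResult, min_frequency: float = 0.4
                       ) -> pd.DataFrame:
    """Consensus feature importance over the LOOCV iterations.

    selection_frequency = times selected / n iterations; relative weight in
    one iteration = |coef| / sum over that iteration's selected features;
    mean_relative_weight averages over the iterations where the feature was
    selected. ``flagged`` marks features at or above ``min_frequency``
    (selected in more than 40% of iterations at the default).
    """
    if not result.iterations:
        raise ValidationError("empty LOOCV result")
    n = len(result.iterations)
    counts: dict[str, int] = {}
    rel_weights: dict[str, list[float]] = {}
    signed: dict[str, list[float]] = {}
    for it in result.iterations:
        total = sum(abs(w) for w in it.weights.values())
        for feat in it.selected_features:
            counts[feat] = counts.get(feat, 0) + 1
            w = it.weights[feat]
            rel_weights.setdefault(feat, []).append(
                abs(w) / total if total > 0 else 0.0)
            signed.setdefault(feat, []).append(w)
    rows = []
    for feat, c in counts.items():
        rows.append({
            "feature": feat,
            "times_selected": c,
            "selection_frequency": c / n,
            "mean_relative_weight": float(np.mean(rel_weights[feat])),
            "mean_weight": float(np.mean(signed[feat])),
        })
    out = pd.DataFrame(rows).set_index("feature")
    out = out.sort_values(["selection_frequency", "mean_relative_weight"],
                          ascending=False)
    out["flagged"] = out["selection_frequency"] >= min_frequency
    out["majority"] = out["times_selected"] >= int(np.ceil(0.4 * n))
    return out


def sweep_n_features(table: FeatureTable, labels: pd.Series,
                     config: PipelineConfig, k_range) -> tuple[int, pd.DataFrame]:
    """Run LOOCV for each k in ``k_range``; return the AUC-optimal k.

    Ties are broken toward the smallest k.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ConfigurationError("empty k range")
    records = []
    for k in k_range:
        cfg = PipelineConfig(n_features_rfe=k, inner_folds=config.inner_folds,
                             grid=config.grid, scoring=config.scoring,
                             decision_threshold=config.decision_threshold,
                             seed=config.seed,
                             preprocess_mode=config.preprocess_mode)
        auc = loocv_run(table, labels, cfg).pooled_auc()
        records.append({"k": k, "pooled_auc": auc})
    curve = pd.DataFrame(records).set_index("k")
    best_k = int(curve["pooled_auc"].idxmax())  # idxmax -> first (smallest) k
    return best_k, curve
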