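"""Pre-processing: fold-change assembly, imputation, scaling, collinearity pruning.

Three steps run before modelling, in this order: iterative (chained-equation)
imputation with a Bayesian ridge estimator, min-max scaling to [0, 1], and
collinearity reduction that keeps one randomly chosen feature from each
group of features whose pairwise Spearman rank correlation exceeds 0.75.

Two usage modes exist. In the reproduction mode the three steps run once on
the full table before cross-validation. In the leakage-safe mode
(:class:`PreprocessModel`) the imputation regressions, scaling ranges and
prune decisions are fitted on the training rows only and applied unchanged
to held-out rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from .containers import FeatureTable, concat_tables, default_meta
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

SPEARMAN_THRESHOLD = 0.75


# --------------------------------------------------------------------------
# Dynamic (fold-change) features
# --------------------------------------------------------------------------

def fold_change_features(plasma: pd.DataFrame, markers=None, week: int = 3,
                         baseline_week: int = 1) -> FeatureTable:
    """Week-``week`` / baseline fold-change features from a long plasma table.

    ``plasma`` has columns ``patient_id, marker, week, value``. A missing or
    non-positive baseline yields a missing entry (imputed downstream) with a
    logged warning. Features are tagged ``kind="fold_change"``.
    """
    required = {"patient_id", "marker", "week", "value"}
    if not required.issubset(plasma.columns):
        raise ValidationError(f"plasma table needs columns {sorted(required)}")
    if markers is None:
        markers = sorted(plasma["marker"].unique())

    wide = plasma.pivot_table(index="patient_id", columns=["marker", "week"],
                              values="value", aggfunc="first")
    cols = {}
    for marker in markers:
        name = f"{marker} FC w{week}"
        try:
            base = wide[(marker, baseline_week)]
            now = wide[(marker, week)]
        except KeyError as exc:
            raise ValidationError(f"marker/week missing from plasma table: {exc}")
        bad = base.isna() | (base <= 0) | now.isna()
        if bad.any():
            logger.warning("%s: %d patients with missing/zero baseline; "
                           "fold change set missing", marker, int(bad.sum()))
        fc = now / base
        fc[bad] = np.nan
        cols[name] = fc
    values = pd.DataFrame(cols)
    values.index.name = "patient_id"
    meta = default_meta(values.columns, source="blood",
                        timepoint=f"week{week}", kind="fold_change")
    meta["marker"] = list(markers)
    return FeatureTable(values, meta)


def assemble_dynamic(baseline: FeatureTable, dynamic: FeatureTable) -> FeatureTable:
    """Column-concatenate baseline and fold-change features (id-checked)."""
    if dynamic.n_features == 0:
        return baseline.copy()
    return concat_tables(baseline, dynamic)


# --------------------------------------------------------------------------
# Imputation
# --------------------------------------------------------------------------

def _check_imputable(values: pd.DataFrame) -> None:
    all_missing_cols = values.columns[values.isna().all(axis=0)]
    if len(all_missing_cols):
        raise ValidationError(
            f"feature(s) entirely missing: {list(all_missing_cols)}")
    all_missing_rows = values.index[values.isna().all(axis=1)]
    if len(all_missing_rows):
        raise ValidationError(
            f"patient(s) entirely missing: {list(all_missing_rows)}")


def make_imputer(max_iter: int = 10, tol: float = 1e-3,
                 seed: int = 0) -> IterativeImputer:
    return IterativeImputer(estimator=BayesianRidge(), max_iter=max_iter,
                            tol=tol, random_state=seed,
                            keep_empty_features=True)


def iterative_impute(table: FeatureTable, max_iter: int = 10,
                     tol: float = 1e-3, seed: int = 0) -> FeatureTable:
    """Chained-equation imputation; observed cells are returned unchanged.

    Each incomplete feature is regressed on all others with a Bayesian ridge
    (penalty inferred from the data), cycling until the largest change falls
    below ``tol`` (relative to the data range) or ``max_iter`` rounds.
    """
    if table.is_complete:
        return table.copy()
    _check_imputable(table.values)
    imputer = make_imputer(max_iter=max_iter, tol=tol, seed=seed)
    filled = imputer.fit_transform(table.values.to_numpy(dtype=float))
    observed = ~table.values.isna().to_numpy()
    # guarantee exact preservation of observed cells
    filled[observed] = table.values.to_numpy(dtype=float)[observed]
    return FeatureTable(pd.DataFrame(filled, index=table.patient_ids,
                                     columns=table.feature_names),
                        table.meta.copy())


# --------------------------------------------------------------------------
# Scaling
# --------------------------------------------------------------------------

def minmax_scale(table: FeatureTable) -> tuple[FeatureTable, pd.DataFrame]:
    """Map each feature to [0, 1] via (x - min) / (max - min).

    A constant feature maps to all zeros. Returns the scaled table and a
    per-feature (min, max) frame for reuse on held-out rows; held-out values
    outside the training range are extrapolated, not clipped.
    """
    if not table.is_complete:
        raise ValidationError("scale requires an imputed (complete) table")
    x = table.to_numpy()
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    params = pd.DataFrame({"min": lo, "max": hi}, index=table.feature_names)
    scaled = apply_minmax(table.values, params)
    return FeatureTable(scaled, table.meta.copy()), params


def apply_minmax(values: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    lo = params["min"].reindex(values.columns).to_numpy()
    hi = params["max"].reindex(values.columns).to_numpy()
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = (values.to_numpy(dtype=float) - lo) / safe
    out[:, span <= 0] = 0.0
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# --------------------------------------------------------------------------
# Collinearity pruning
# --------------------------------------------------------------------------

@dataclass
class PruneReport:
    """Record of collinearity reduction: who was dropped in favour of whom."""

    threshold: float = SPEARMAN_THRESHOLD
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    #: connected components of the |rho| > threshold graph, one list each
    groups: list[list[str]] = field(default_factory=list)

    @property
    def dropped_features(self) -> list[str]:
        return [d for _, d, _ in self.dropped]


def spearman_matrix(values: pd.DataFrame) -> np.ndarray:
    """All-pairs Spearman rho (average ranks for ties)."""
    p = values.shape[1]
    if p < 2:
        return np.eye(p)
    rho = stats.spearmanr(values.to_numpy(dtype=float), axis=0).statistic
    if np.ndim(rho) == 0:           # scipy collapses the 2-column case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.asarray(rho, dtype=float)
    # constant columns yield NaN correlations; treat as uncorrelated
    np.fill_diagonal(rho, 1.0)
    return np.nan_to_num(rho, nan=0.0)


def spearman_prune(table: FeatureTable, rho: float = SPEARMAN_THRESHOLD,
                   seed: int = 0, use_abs: bool = True
                   ) -> tuple[FeatureTable, PruneReport]:
    """Drop all but one feature from each collinear group.

    A collinear group is a connected component of the graph whose edges join
    features with |Spearman rho| strictly above ``rho`` (signed rho when
    ``use_abs`` is False). One survivor per group is chosen uniformly by the
    seeded RNG; ties at exactly the threshold are retained.
    """
    if table.n_patients < 2:
        raise ValidationError("pruning needs at least 2 patients")
    corr = spearman_matrix(table.values)
    strength = np.abs(corr) if use_abs else corr
    # strictly "above" the threshold; 1e-12 guard so a correlation equal to
    # the threshold up to floating-point rank arithmetic is retained
    adj = (strength - rho) > 1e-12
    np.fill_diagonal(adj, False)

    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    rng = np.random.default_rng(seed)
    names = list(table.feature_names)
    keep: list[str] = []
    report = PruneReport(threshold=rho)
    for c in range(n_comp):
        members = [names[j] for j in np.where(comp == c)[0]]
        if len(members) == 1:
            keep.append(members[0])
            continue
        survivor = members[int(rng.integers(len(members)))]
        keep.append(survivor)
        report.groups.append(members)
        si = names.index(survivor)
        for m in members:
            if m != survivor:
                report.dropped.append((survivor, m, float(corr[si, names.index(m)])))
    keep = [f for f in names if f in set(keep)]  # preserve column order
    return table.select_features(keep), report


# --------------------------------------------------------------------------
# Pipelines
# --------------------------------------------------------------------------

def preprocess_table(table: FeatureTable, seed: int = 0, rho: float = SPEARMAN_THRESHOLD,
                     max_iter: int = 10, tol: float = 1e-3
                     ) -> tuple[FeatureTable, pd.DataFrame, PruneReport]:
    """Impute -> scale -> prune on the full table (reproduction mode)."""
    imputed = iterative_impute(table, max_iter=max_iter, tol=tol, seed=seed)
    scaled, params = minmax_scale(imputed)
    pruned, report = spearman_prune(scaled, rho=rho, seed=seed)
    return pruned, params, report


class PreprocessModel:
    """Leakage-safe preprocessing: fit on training rows, apply to new rows."""

    def __init__(self, seed: int = 0, rho: float = SPEARMAN_THRESHOLD,
                 max_iter: int = 10, tol: float = 1e-3):
        self.seed = seed
        self.rho = rho
        self.max_iter = max_iter
        self.tol = tol

    def fit_transform(self, table: FeatureTable) -> FeatureTable:
        _check_imputable(table.values)
        self._columns = list(table.feature_names)
        self._imputer = make_imputer(self.max_iter, self.tol, self.seed)
        filled = self._imputer.fit_transform(table.to_numpy())
        observed = ~table.values.isna().to_numpy()
        filled[observed] = table.to_numpy()[observed]
        complete = FeatureTable(
            pd.DataFrame(filled, index=table.patient_ids, columns=table.feature_names),
            table.meta.copy())
        scaled, self.scale_params_ = minmax_scale(complete)
        pruned, self.prune_report_ = spearman_prune(scaled, rho=self.rho,
                                                    seed=self.seed)
        self.kept_features_ = list(pruned.feature_names)
        self._meta = pruned.meta
        return pruned

    def transform(self, table: FeatureTable) -> FeatureTable:
        vals = table.values[self._columns]
        filled = self._imputer.transform(vals.to_numpy(dtype=float))
        observed = ~vals.isna().to_numpy()
        filled[observed] = vals.to_numpy(dtype=float)[observed]
        frame = pd.DataFrame(filled, index=vals.index, columns=self._columns)
        scaled = apply_minmax(frame, self.scale_params_)
        return FeatureTable(scaled[self.kept_features_], self._meta)
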