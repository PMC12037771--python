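"""Transcriptomic signature scoring, quartile stratification and survival.

A gene signature score for a patient is the mean, over the signature's
genes, of the per-gene z-score of normalised expression across patients:
z_gp = (x_gp - mean_g) / sd_g, score_p = mean_g(z_gp). Response and
non-response signatures built from a differential-expression table (padj <
0.05 and log2 fold change > 2 or < -2 respectively) combine into a
quartile stratification: patients in the top quartile of the response score
and the bottom quartile of the non-response score form the "hi" stratum,
the mirror set the "lo" stratum, and progression-free survival is compared
between strata with Kaplan-Meier medians and a log-rank test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

PADJ_MAX = 0.05
LFC_MIN = 2.0


@dataclass
class GeneSignature:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has no genes")


@dataclass
class StratificationResult:
    hi_ids: list
    lo_ids: list
    median_pfs_hi: float | None = None
    median_pfs_lo: float | None = None
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Signature registry (named published signatures, shipped with the package)
# --------------------------------------------------------------------------

def _registry() -> dict:
    text = resources.files("vttml.data").joinpath("signatures.json").read_text()
    return json.loads(text)


def list_signatures() -> list[str]:
    return sorted(_registry())


def load_signature(name: str) -> GeneSignature:
    reg = _registry()
    if name not in reg:
        raise ValidationError(
            f"unknown signature {name!r}; available: {sorted(reg)}")
    return GeneSignature(name=name, genes=list(reg[name]["genes"]))


# --------------------------------------------------------------------------
# Gene filtering and signature construction
# --------------------------------------------------------------------------

def gene_inclusion_filter(counts: pd.DataFrame) -> pd.Index:
    """Genes with max count strictly > 10 and counts > 0 in strictly more
    than half of the biopsies (both cutoffs exclusive)."""
    x = counts.to_numpy()
    if (x < 0).any():
        raise ValidationError("negative counts")
    max_ok = x.max(axis=1) > 10
    frac_nonzero = (x > 0).mean(axis=1)
    return counts.index[max_ok & (frac_nonzero > 0.5)]


def build_nax_signatures(de: pd.DataFrame, padj_max: float = PADJ_MAX,
                         lfc_min: float = LFC_MIN
                         ) -> tuple[GeneSignature, GeneSignature]:
    """Response / non-response signatures from a DE table.

    ``de`` is indexed by gene with columns ``lfc`` (log2 fold change,
    responder vs non-responder) and ``padj``. Response = padj < padj_max and
    lfc > lfc_min; non-response = padj < padj_max and lfc < -lfc_min (all
    strict).
    """
    for col in ("lfc", "padj"):
        if col not in de.columns:
            raise ValidationError(f"DE table missing column {col!r}")
    if de.empty:
        raise ValidationError("empty DE table")
    sig = de["padj"] < padj_max
    up = de.index[sig & (de["lfc"] > lfc_min)].tolist()
    down = de.index[sig & (de["lfc"] < -lfc_min)].tolist()
    if not up or not down:
        raise ValidationError(
            f"no genes pass padj < {padj_max} with |lfc| > {lfc_min} in "
            f"{'response' if not up else 'non-response'} direction")
    return (GeneSignature("response", up), GeneSignature("non_response", down))


def signature_score(expr: pd.DataFrame, sig: GeneSignature) -> pd.Series:
    """Mean per-gene z-score over the signature genes present in ``expr``.

    ``expr`` is gene x patient on a normalised (variance-stabilised) scale.
    Genes absent from the matrix, and zero-variance genes, are dropped with
    a warning; sample (n-1) standard deviation.
    """
    if expr.shape[1] < 2:
        raise ValidationError("need at least 2 patients to z-score")
    present = [g for g in sig.genes if g in expr.index]
    dropped = sorted(set(sig.genes) - set(present))
    if dropped:
        logger.warning("signature %s: %d gene(s) absent from matrix: %s",
                       sig.name, len(dropped), dropped[:10])
    if not present:
        raise ValidationError(f"no genes of signature {sig.name!r} present")
    sub = expr.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        logger.warning("signature %s: dropping zero-variance genes %s",
                       sig.name, flat)
        sub = sub.drop(index=flat)
        sd = sd.drop(index=flat)
        if sub.empty:
            raise ValidationError(
                f"all present genes of {sig.name!r} have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename(f"{sig.name}_score")


# --------------------------------------------------------------------------
# Quartile stratification and survival
# --------------------------------------------------------------------------

def quartile_stratify(resp_scores: pd.Series, nonresp_scores: pd.Series
                      ) -> tuple[list, list]:
    """hi = top quartile of response AND bottom quartile of non-response;
    lo = the mirror set. Quartiles are linear-interpolation sample
    quantiles, boundaries inclusive."""
    if not resp_scores.index.equals(nonresp_scores.index):
        nonresp_scores = nonresp_scores.reindex(resp_scores.index)
        if nonresp_scores.isna().any():
            raise ValidationError("score vectors cover different patients")
    n = len(resp_scores)
    if n < 4:
        raise ValidationError("need at least 4 patients to form quartiles")
    r_q1, r_q3 = np.quantile(resp_scores, [0.25, 0.75])
    n_q1, n_q3 = np.quantile(nonresp_scores, [0.25, 0.75])
    hi = resp_scores.index[(resp_scores >= r_q3) & (nonresp_scores <= n_q1)]
    lo = resp_scores.index[(resp_scores <= r_q1) & (nonresp_scores >= n_q3)]
    overlap = hi.intersection(lo)
    if len(overlap):
        # only possible in degenerate (near-constant) score vectors
        hi = hi.difference(overlap)
        lo = lo.difference(overlap)
    return list(hi), list(lo)


def _check_survival(surv: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in surv.columns:
            raise ValidationError(f"survival table missing column {col!r}")
    if surv.empty:
        raise ValidationError("empty survival table")
    if (surv["time"] < 0).any():
        raise ValidationError("negative survival time")
    return surv


def km_median(surv: pd.DataFrame) -> float | None:
    """Kaplan-Meier median: earliest time with survival <= 0.5, or None if
    the curve never reaches 0.5."""
    surv = _check_survival(surv)
    km = KaplanMeierFitter().fit(surv["time"], surv["event"])
    med = km.median_survival_time_
    return None if np.isinf(med) else float(med)


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame
                 ) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    a, b = _check_survival(group_a), _check_survival(group_b)
    if a["event"].sum() + b["event"].sum() == 0:
        raise ValidationError("no events in either group")
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def stratify_survival(resp_scores: pd.Series, nonresp_scores: pd.Series,
                      survival: pd.DataFrame) -> StratificationResult:
    """Quartile stratification plus KM medians and log-rank comparison.

    ``survival`` must carry a ``patient_id`` column (or be indexed by it)
    alongside ``time`` and ``event``.
    """
    if "patient_id" in survival.columns:
        survival = survival.set_index("patient_id")
    hi, lo = quartile_stratify(resp_scores, nonresp_scores)
    result = StratificationResult(hi_ids=hi, lo_ids=lo)
    surv_hi = survival.loc[[p for p in hi if p in survival.index]]
    surv_lo = survival.loc[[p for p in lo if p in survival.index]]
    if len(surv_hi) and len(surv_lo):
        result.median_pfs_hi = km_median(surv_hi)
        result.median_pfs_lo = km_median(surv_lo)
        stat, p = logrank_test(surv_hi, surv_lo)
        result.logrank_statistic, result.logrank_p = stat, p
    result.extras = {"n_hi": len(hi), "n_lo": len(lo)}
    return result
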