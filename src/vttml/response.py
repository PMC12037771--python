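"""Venous tumour thrombus (VTT) response evaluation.

Total VTT length is the sum of three MRI-measured segments: thrombus in the
renal vein (RV), thrombus in the inferior vena cava above the renal vein
ostium, and thrombus below it.  Response is the percent change of total
length at the end-of-treatment scan (week 9) versus baseline (week 1),
(LT - LB) / LB * 100; a patient with a reduction of more than 30%
(percent change strictly below -30) is a responder.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: Percent-reduction cutoff defining response. The strict inequality means a
#: change of exactly -30.0% is *not* a response ("more than 30% reduction").
RESPONSE_THRESHOLD = 30.0

VTT_COLUMNS = ["patient_id", "week", "rv_length", "ivc_above", "ivc_below"]


def total_length(rv_length: float, ivc_above: float, ivc_below: float) -> float:
    """Total VTT length (mm): sum of the three segment lengths."""
    segments = (rv_length, ivc_above, ivc_below)
    for s in segments:
        if not math.isfinite(s):
            raise ValidationError(f"non-finite segment length: {s}")
        if s < 0:
            raise ValidationError(f"negative segment length: {s}")
    return float(sum(segments))


def percent_change(lt: float, lb: float) -> float:
    """Signed percent change of length ``lt`` versus baseline ``lb``.

    Negative values are shrinkage. The baseline must be strictly positive.
    """
    if not (math.isfinite(lt) and math.isfinite(lb)):
        raise ValidationError("non-finite length")
    if lb <= 0:
        raise ValidationError(f"baseline length must be > 0, got {lb}")
    return (lt - lb) / lb * 100.0


def classify_responder(pct: float, threshold: float = RESPONSE_THRESHOLD) -> bool:
    """True iff ``pct`` is strictly below ``-threshold`` percent."""
    if not math.isfinite(pct):
        raise ValidationError(f"non-finite percent change: {pct}")
    return pct < -threshold


def classify_cohort(
    vtt: pd.DataFrame,
    baseline_week: int = 1,
    response_week: int = 9,
    threshold: float = RESPONSE_THRESHOLD,
) -> pd.DataFrame:
    """Compute per-patient percent change and responder label from VTT lengths.

    Parameters
    ----------
    vtt
        Long-format table with columns ``patient_id, week, rv_length,
        ivc_above, ivc_below`` (mm), one row per patient per scan week.

    Returns
    -------
    DataFrame indexed by patient id with ``pct_change_w9`` and ``responder``.
    Patients missing the baseline or response-week scan are excluded with a
    logged warning.
    """
    missing_cols = [c for c in VTT_COLUMNS if c not in vtt.columns]
    if missing_cols:
        raise ValidationError(f"vtt table missing columns: {missing_cols}")

    records = []
    for pid, grp in vtt.groupby("patient_id", sort=True):
        by_week = grp.set_index("week")
        if baseline_week not in by_week.index or response_week not in by_week.index:
            logger.warning(
                "patient %s missing week-%d or week-%d scan; excluded",
                pid, baseline_week, response_week,
            )
            continue
        lb = total_length(*by_week.loc[baseline_week, ["rv_length", "ivc_above", "ivc_below"]])
        lt = total_length(*by_week.loc[response_week, ["rv_length", "ivc_above", "ivc_below"]])
        pct = percent_change(lt, lb)
        records.append((pid, pct, classify_responder(pct, threshold)))

    out = pd.DataFrame(records, columns=["patient_id", "pct_change_w9", "responder"])
    out = out.set_index("patient_id")
    out["responder"] = out["responder"].astype(bool)
    out["pct_change_w9"] = out["pct_change_w9"].astype(float)
    return out


def labels_series(labels: pd.DataFrame) -> pd.Series:
    """Binary 0/1 responder vector from a ``classify_cohort`` output."""
    return labels["responder"].astype(int)
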