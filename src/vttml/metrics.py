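"""Classification metrics over out-of-fold prediction scores."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import ValidationError


def _check(scores, labels, need_both_classes=True, need_positive=False):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and aligned")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("non-finite score")
    if not np.isin(labels, [0, 1]).all():
        raise ValidationError("labels must be binary 0/1")
    if need_both_classes and len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")
    if need_positive and labels.sum() == 0:
        raise ValidationError("at least one positive label required")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """ROC AUC = Mann-Whitney concordance, ties credited 0.5."""
    scores, labels = _check(scores, labels)
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """Precision-recall AUC in average-precision (step-integral) form."""
    scores, labels = _check(scores, labels, need_both_classes=False, need_positive=True)
    return float(average_precision_score(labels, scores))


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics with a positive call at score > threshold."""
    scores, labels = _check(scores, labels)
    pred = scores > threshold
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    fp = int(np.sum(pred & neg))
    tn = int(np.sum(~pred & neg))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "accuracy": (tp + tn) / len(labels),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
    }


def metrics_block(scores, labels, threshold: float = 0.5) -> dict:
    """AUC ROC, AU PRC and threshold metrics in one dict (run.json block)."""
    block = {"auc_roc": roc_auc(scores, labels), "au_prc": pr_auc(scores, labels)}
    block.update(threshold_metrics(scores, labels, threshold))
    return block
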