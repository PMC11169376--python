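"""Macro-averaged one-vs-rest classification metrics.

For each class ``c`` the confusion matrix is collapsed to TP/FP/TN/FN and

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    recall      = TP / (TP + FN)
    F1          = 2 * precision * recall / (precision + recall)

are computed; the macro value is the unweighted mean over classes.  A
per-class metric with a zero denominator is defined as 0 and the class is
flagged as degenerate.  Note that for two classes, macro specificity and
macro recall are the same quantity (class 0's specificity is class 1's
recall and vice versa).
"""

from __future__ import annotations

import numpy as np

__all__ = ["confusion_matrix", "macro_metrics", "METRIC_NAMES"]

METRIC_NAMES = ("accuracy", "precision", "specificity", "recall", "f1")


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts with true classes on rows, predicted classes on columns."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    if ((y_true < 0) | (y_true >= n_classes) | (y_pred < 0)
            | (y_pred >= n_classes)).any():
        raise ValueError("labels outside 0..n_classes-1")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def macro_metrics(confusion: np.ndarray) -> dict:
    """Per-class and macro metrics from a square confusion matrix."""
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion entries must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix has no observations")
    k = cm.shape[0]
    per_class = {m: np.zeros(k) for m in METRIC_NAMES}
    degenerate = []
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        acc = (tp + tn) / total
        prec = _safe_div(tp, tp + fp)
        spec = _safe_div(tn, tn + fp)
        rec = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * prec * rec, prec + rec)
        if tp + fn == 0 or tp + fp == 0:
            degenerate.append(c)
        for m, v in zip(METRIC_NAMES, (acc, prec, spec, rec, f1)):
            per_class[m][c] = v
    macro = {m: float(per_class[m].mean()) for m in METRIC_NAMES}
    return {"macro": macro, "per_class": per_class,
            "degenerate_classes": degenerate, "n": int(total)}
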