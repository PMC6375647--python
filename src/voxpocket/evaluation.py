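"""Classification metrics: confusion counts, ACC/PPV/TNR/TPR/FPR, MCC, ROC/AUC.

Multi-class results are evaluated one-vs-rest per class, scoring each class
with its softmax probability.  Metrics with a zero denominator are reported
as missing (NaN), never coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(true_labels, predicted_labels, positive) -> ConfusionCounts:
    """One-vs-rest confusion counts for the named positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"label lengths differ: {t.shape} vs {p.shape}")
    tpos, ppos = t == positive, p == positive
    return ConfusionCounts(
        TP=int(np.sum(tpos & ppos)),
        TN=int(np.sum(~tpos & ~ppos)),
        FP=int(np.sum(~tpos & ppos)),
        FN=int(np.sum(tpos & ~ppos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, specificity, sensitivity and fall-out.

    ACC = (TP+TN)/(TP+FP+TN+FN), PPV = TP/(TP+FP), TNR = TN/(TN+FP),
    TPR = TP/(TP+FN), FPR = FP/(FP+TN).  Undefined ratios are NaN.
    """
    return {
        "ACC": _ratio(c.TP + c.TN, c.total),
        "PPV": _ratio(c.TP, c.TP + c.FP),
        "TNR": _ratio(c.TN, c.TN + c.FP),
        "TPR": _ratio(c.TP, c.TP + c.FN),
        "FPR": _ratio(c.FP, c.FP + c.TN),
    }


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient, in [-1, 1]; NaN if any marginal is zero."""
    denom = ((c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    if denom == 0:
        return float("nan")
    return (c.TN * c.TP - c.FP * c.FN) / np.sqrt(float(denom))


@dataclass
class ROCCurve:
    """ROC points (FPR, TPR) from (0,0) to (1,1), with the thresholds swept."""

    thresholds: np.ndarray   # descending score thresholds, one per interior point
    fpr: np.ndarray
    tpr: np.ndarray


def roc_auc(scores, labels) -> tuple[ROCCurve, float]:
    """ROC curve and trapezoidal AUC for binary labels scored high=positive.

    Equal scores are grouped at a single threshold, so the trapezoidal area
    equals the Mann-Whitney pair statistic with ties counted one half.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group tied scores: cumulative counts at the last index of each tie group
    distinct = np.nonzero(np.diff(s))[0]
    boundaries = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(y)[boundaries]
    fp = np.cumsum(~y)[boundaries]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(s[boundaries], fpr, tpr), auc


def roc_points_frame(curve: ROCCurve) -> pd.DataFrame:
    """ROC points as a plottable table (threshold NaN for the (0,0) anchor)."""
    thresholds = np.r_[np.nan, curve.thresholds]
    return pd.DataFrame({"threshold": thresholds, "fpr": curve.fpr,
                         "tpr": curve.tpr})


def summarize_predictions(preds: pd.DataFrame) -> pd.DataFrame:
    """Per-class one-vs-rest metric table from a prediction frame.

    ``preds`` columns: ``true`` (integer class) and ``prob_<c>`` for each
    class; hard labels are the argmax over probabilities.
    """
    prob_cols = [c for c in preds.columns if c.startswith("prob_")]
    classes = [int(c.split("_", 1)[1]) for c in prob_cols]
    probs = preds[prob_cols].to_numpy()
    true = preds["true"].to_numpy()
    hard = np.array(classes)[probs.argmax(axis=1)]
    rows = []
    for j, cls in enumerate(classes):
        c = confusion(true, hard, cls)
        row = {"class": cls, **classification_metrics(c), "MCC": mcc(c)}
        try:
            _, row["AUC"] = roc_auc(probs[:, j], true == cls)
        except ValueError:
            row["AUC"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
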