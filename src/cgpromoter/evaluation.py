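"""Binary-classifier evaluation: confusion counts, Sn/Sp/Acc/MCC, ROC/AUC.

Sensitivity Sn = TP/(TP+FN) measures promoter recall, specificity
Sp = TN/(TN+FP) non-promoter recall; accuracy is their count-weighted
mean; the Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)) summarises the
whole table in [-1, 1] and is set to 0 (logged) when any denominator
factor vanishes. Report outputs print two-decimal percentages; the raw
fractions are always available on the objects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .encoder import FeatureMatrix
from .model import CVPlan, TrainedModel, train_final, predict

logger = logging.getLogger("cgpromoter")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("all confusion counts are zero")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    """Sn/Sp/Acc as fractions in [0,1], MCC in [-1,1]."""

    sn: float
    sp: float
    acc: float
    mcc: float

    def as_percent(self) -> dict[str, float]:
        """Two-decimal percentages, matching standard report style
        (MCC is conventionally printed as a percentage too)."""
        return {
            "Sn": round(self.sn * 100, 2),
            "Sp": round(self.sp * 100, 2),
            "Acc": round(self.acc * 100, 2),
            "MCC": round(self.mcc * 100, 2),
        }

    def format_row(self) -> str:
        p = self.as_percent()
        return "\t".join(f"{p[k]:.2f}" for k in ("Sn", "Sp", "Acc", "MCC"))


@dataclass
class ROCCurve:
    """Threshold-swept ROC points and the trapezoidal area under them."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion(labels, predicted) -> ConfusionCounts:
    """Count TP/FP/TN/FN for binary labels and predictions."""
    y = np.asarray(labels)
    p = np.asarray(predicted)
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Sn, Sp, Acc and MCC from a confusion table."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.positives == 0 or counts.negatives == 0:
        raise ValueError("Sn/Sp need at least one sample of each class")
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / (tp + fp + tn + fn)
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if denom == 0:
        logger.warning("MCC denominator factor is zero; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


def roc_auc(labels, scores) -> ROCCurve:
    """ROC curve over score thresholds and trapezoidal AUC.

    Tied scores are collapsed into one threshold step, which makes the
    trapezoidal area equal the probabilistic AUC
    P(score_pos > score_neg) + 0.5 P(equal).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def cross_validated_report(
    matrix: FeatureMatrix,
    params: dict,
    plan: CVPlan,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-fold Sn/Sp/Acc/MCC/AUC plus a mean row and a pooled-score AUC.

    For each fold a forest with ``params`` is trained on the other folds
    and evaluated on the held-out one. The summary row is the arithmetic
    mean of the fold rows; 'AUC (pooled)' on that row is instead computed
    once from all held-out scores pooled together (the two views of a
    cross-validated ROC).
    """
    if matrix.labels is None:
        raise ValueError("cross-validation needs labels")
    y = matrix.labels
    rows = []
    pooled_scores = np.empty(len(y), dtype=float)
    for f, (train_idx, test_idx) in enumerate(plan.split(), start=1):
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError(f"fold {f} is single-class; cannot evaluate")
        sub = FeatureMatrix(
            matrix.values[train_idx], matrix.feature_ids, labels=y[train_idx]
        )
        model = train_final(sub, params, seed=seed)
        held = FeatureMatrix(matrix.values[test_idx], matrix.feature_ids)
        pred, scores = predict(model, held)
        pooled_scores[test_idx] = scores
        m = metrics(confusion(y[test_idx], pred))
        p = m.as_percent()
        p["AUC"] = round(roc_auc(y[test_idx], scores).auc * 100, 2)
        rows.append(pd.Series(p, name=f"fold {f}"))
    df = pd.DataFrame(rows)
    mean_row = df.mean(axis=0).round(2)
    mean_row.name = "mean"
    df = pd.concat([df, mean_row.to_frame().T])
    df["AUC (pooled)"] = np.nan
    df.loc["mean", "AUC (pooled)"] = round(roc_auc(y, pooled_scores).auc * 100, 2)
    return df
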