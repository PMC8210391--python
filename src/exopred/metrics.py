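"""Binary-classification performance measures.

Threshold-dependent measures from a confusion table:

    SE  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    ACC = 100 × (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP·TN − FP·FN) / sqrt((TN+FN)(TP+FN)(TN+FP)(TP+FP))

plus the threshold-free AUC of the ROC curve (sensitivity against
1 − specificity). AUC is computed by Mann–Whitney pair counting — the
fraction of (positive, negative) score pairs ranked concordantly, ties
counted half — which equals trapezoidal integration of the ROC curve over
all distinct thresholds.

A measure whose denominator is zero is reported as NaN and listed in the
report's ``undefined`` set rather than raising, so fold aggregation can skip
it with a logged count.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata


class MetricsError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise MetricsError(f"{name} must be a non-negative integer, got {v}")
        if self.tp + self.fn + self.tn + self.fp == 0:
            raise MetricsError("empty confusion table")

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise MetricsError("y_true / y_pred length mismatch")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
        )


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    se: float
    sp: float
    acc_percent: float
    mcc: float
    auc: Optional[float] = None
    n_pos: int = 0
    n_neg: int = 0
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        return {
            "se": self.se,
            "sp": self.sp,
            "acc_percent": self.acc_percent,
            "mcc": self.mcc,
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "undefined": sorted(self.undefined),
        }


def confusion_metrics(c: ConfusionCounts) -> MetricsReport:
    """SE, SP, ACC and MCC from a confusion table (AUC left unset)."""
    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    se = ratio(c.tp, c.tp + c.fn, "se")
    sp = ratio(c.tn, c.tn + c.fp, "sp")
    acc = 100.0 * (c.tp + c.tn) / (c.tp + c.fp + c.tn + c.fn)
    denom = (
        (c.tn + c.fn) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp)
    )
    if denom == 0:
        undefined.add("mcc")
        mcc = math.nan
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricsReport(
        se=se,
        sp=sp,
        acc_percent=acc,
        mcc=mcc,
        n_pos=c.tp + c.fn,
        n_neg=c.tn + c.fp,
        undefined=frozenset(undefined),
    )


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise MetricsError("scores/labels must be 1-D and of equal length")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise MetricsError("both classes must be present for ROC analysis")
    return s, y


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Equals (concordant pairs + 0.5 × tied pairs) / (n_pos × n_neg).
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    ranks = rankdata(s)  # mid-ranks handle ties as half-concordant
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points (1−SP, SE, thresholds) over all distinct score thresholds.

    The call "score ≥ threshold → positive" is swept from above the maximum
    score (SE = 1−SP = 0) down through every distinct score (ending at
    SE = 1−SP = 1).
    """
    s, y = _check_scores_labels(scores, labels)
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    tp_cum = np.cumsum(y_sorted == 1)
    fp_cum = np.cumsum(y_sorted == 0)
    # keep only the last index of each run of tied scores
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tp_cum[distinct] / n_pos]
    fpr = np.r_[0.0, fp_cum[distinct] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return fpr, tpr, thresholds


def roc_auc_trapezoid(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by trapezoidal integration of the SE vs 1−SP curve."""
    fpr, tpr, _ = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def evaluate_predictions(
    y_true: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> MetricsReport:
    """Full report: thresholded confusion measures plus AUC."""
    s, y = _check_scores_labels(scores, y_true)
    calls = (s >= threshold).astype(int)
    report = confusion_metrics(ConfusionCounts.from_predictions(y, calls))
    return dataclasses.replace(report, auc=roc_auc(s, y))


def write_roc_points(scores, labels, path) -> None:
    fpr, tpr, thr = roc_curve(scores, labels)
    with open(path, "w") as fh:
        fh.write("threshold\tfpr\tse\n")
        for t, f, se in zip(thr, fpr, tpr):
            fh.write(f"{t}\t{f:.6f}\t{se:.6f}\n")
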