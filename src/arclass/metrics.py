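"""Confusion-matrix algebra and performance statistics for unbalanced screens.

The report covers the standard rates (specificity, sensitivity, accuracy,
PPV, NPV — all on the 0-100 percent scale used in screening tables), the
Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP)),

the positive/negative likelihood ratios +LR = SE/(1-SP), -LR = (1-SE)/SP,
and the balanced classification rate BCR = (SE+SP)/2 * (1 - |SE - SP|);
SE and SP enter the ratio-based statistics as fractions.  ROC AUC uses the
Mann-Whitney rank statistic with midrank tie handling, which matters here
because the "no docking pose" sentinel places many compounds at exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
]

METRIC_COLUMNS = ("SP", "SE", "Acc", "MCC", "NPV", "PPV", "plusLR", "minusLR", "BCR")


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def n_positive(self) -> int:
        return self.TP + self.FN

    @property
    def n_negative(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class MetricsReport:
    """SP/SE/Acc/PPV/NPV in percent; MCC in [-1, 1]; LRs as ratios; BCR in [0, 1]."""

    SP: float
    SE: float
    Acc: float
    MCC: float
    NPV: float
    PPV: float
    plusLR: float
    minusLR: float
    BCR: float
    mcc_degenerate: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(labels, preds) -> ConfusionMatrix:
    """Exact confusion counts; class 1 is the positive (binder) class."""
    labels = np.asarray(labels).astype(int)
    preds = np.asarray(preds).astype(int)
    if labels.shape != preds.shape:
        raise ValueError(
            f"labels and predictions differ in shape: {labels.shape} vs {preds.shape}"
        )
    if labels.size == 0:
        raise ValueError("empty label vector")
    for name, v in (("labels", labels), ("predictions", preds)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    tp = int(np.sum((labels == 1) & (preds == 1)))
    tn = int(np.sum((labels == 0) & (preds == 0)))
    fp = int(np.sum((labels == 0) & (preds == 1)))
    fn = int(np.sum((labels == 1) & (preds == 0)))
    return ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        return math.nan
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Full statistics suite from one confusion matrix.

    Degenerate denominators are handled explicitly: a zero factor under the
    MCC square root yields MCC = 0 with ``mcc_degenerate`` flagged; a perfect
    specificity makes +LR infinite (reported as ``inf``); an empty predicted
    class leaves PPV or NPV as NaN.
    """
    tp, tn, fp, fn = cm.TP, cm.TN, cm.FP, cm.FN
    sp = _safe_div(tn, tn + fp)
    se = _safe_div(tp, tp + fn)
    acc = (tp + tn) / cm.total
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)

    mcc_den = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    degenerate = mcc_den == 0
    if degenerate:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den)

    if math.isnan(sp) or math.isnan(se):
        plus_lr = minus_lr = bcr = math.nan
    else:
        plus_lr = math.inf if sp == 1.0 else se / (1.0 - sp)
        minus_lr = math.nan if sp == 0.0 else (1.0 - se) / sp
        bcr = (se + sp) / 2.0 * (1.0 - abs(se - sp))

    to_pct = lambda v: v * 100.0 if not math.isnan(v) else v
    return MetricsReport(
        SP=to_pct(sp),
        SE=to_pct(se),
        Acc=to_pct(acc),
        MCC=mcc,
        NPV=to_pct(npv),
        PPV=to_pct(ppv),
        plusLR=plus_lr,
        minusLR=minus_lr,
        BCR=bcr,
        mcc_degenerate=degenerate,
    )


def roc_auc(scores, labels, orientation: str = "lower") -> float:
    """Rank-based (Mann-Whitney) ROC AUC with midrank tie handling.

    ``orientation="lower"`` means a lower score indicates the positive class,
    the convention for docking energies (more negative = stronger predicted
    binding); ``"higher"`` is the usual probability-like convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if orientation not in ("lower", "higher"):
        raise ValueError("orientation must be 'lower' or 'higher'")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    oriented = -scores if orientation == "lower" else scores
    ranks = rankdata(oriented)  # midranks for ties
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
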