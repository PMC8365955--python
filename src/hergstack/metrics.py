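"""Binary-classification metric suite for hERG blockade evaluation.

Positive class = hERG blocker. The suite mirrors the standard confusion-matrix
statistics used throughout the hERG-prediction literature: sensitivity,
specificity, negative/positive predictive value, raw and balanced accuracy,
Matthews correlation coefficient and AUC-ROC. Metrics with a zero denominator
are reported as ``None`` (printed "NA") rather than coerced to 0, preserving
the reporting convention of published comparison tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "compute_classification_metrics",
    "auc_roc",
    "percent_improvement",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Exact confusion-matrix counts for a binary evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """One evaluation row: rates in [0,1], MCC in [-1,1], ``None`` marks NA."""

    sen: Optional[float] = None
    spe: Optional[float] = None
    npv: Optional[float] = None
    ppv: Optional[float] = None
    acc: Optional[float] = None
    mcc: Optional[float] = None
    b_acc: Optional[float] = None
    auc: Optional[float] = None

    #: canonical column order of published comparison tables
    FIELDS = ("mcc", "npv", "acc", "ppv", "spe", "sen", "b_acc", "auc")

    def as_dict(self, ndigits: int | None = 3) -> dict:
        out = {}
        for f in self.FIELDS:
            v = getattr(self, f)
            if v is not None and ndigits is not None:
                v = round(v, ndigits)
            out[f.upper().replace("_", "-")] = v
        return out

    def formatted(self, ndigits: int = 3) -> dict:
        """Dict with NA strings, for CSV emission."""
        return {
            k: ("NA" if v is None else f"{v:.{ndigits}f}")
            for k, v in self.as_dict(ndigits=None).items()
        }


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary labels and binary predictions."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def compute_classification_metrics(c: ConfusionCounts) -> MetricReport:
    """Threshold metrics from counts; AUC is left unset (needs scores).

    SEN = TP/(TP+FN), SPE = TN/(TN+FP), NPV = TN/(TN+FN), PPV = TP/(TP+FP),
    ACC = (TP+TN)/total, B-ACC = (SEN+SPE)/2 and

        MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Any metric whose denominator is zero comes back as ``None``.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    sen = _ratio(tp, tp + fn)
    spe = _ratio(tn, tn + fp)
    npv = _ratio(tn, tn + fn)
    ppv = _ratio(tp, tp + fp)
    acc = _ratio(tp + tn, c.total)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / math.sqrt(mcc_den)
    b_acc = None if (sen is None or spe is None) else (sen + spe) / 2
    return MetricReport(
        sen=sen, spe=spe, npv=npv, ppv=ppv, acc=acc, mcc=mcc, b_acc=b_acc
    )


def auc_roc(
    y_true: Sequence[int], scores: Sequence[float]
) -> Optional[float]:
    """Area under the ROC curve via the tie-corrected rank statistic.

    Equals the probability that a uniformly random positive receives a higher
    score than a uniformly random negative, counting ties as one half
    (Mann-Whitney U / (n_pos * n_neg)). Returns ``None`` with a warning when
    only one class is present.
    """
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ValueError("length mismatch between labels and scores")
    n_pos = int((yt == 1).sum())
    n_neg = int((yt == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined: only one class present", stacklevel=2)
        return None
    ranks = rankdata(s)  # average ranks handle ties
    u = ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def percent_improvement(candidate: float, baseline: float) -> Optional[float]:
    """Relative change of ``candidate`` over ``baseline`` in percent.

    100 * (candidate - baseline) / baseline; ``None`` when the baseline is 0.
    """
    if baseline == 0:
        return None
    return 100.0 * (candidate - baseline) / baseline
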