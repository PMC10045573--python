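"""Confusion-matrix metrics for segmentation masks and label vectors.

All metrics reduce to the four counts (TP, FP, FN, TN). DSC and JSC obey the
algebraic identity JSC = DSC / (2 - DSC); the symmetric volume difference is
SVD = 1 - DSC. Zero-denominator cases get a deterministic conventional value
(1.0 where the ideal count is trivially achieved, 0.0 for error rates, 0 for
MCC with a zero marginal) and are flagged in the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .exceptions import DomainError, ShapeError
from .imaging import BinaryMask

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "compute_metrics", "dice", "evaluate_masks"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """One value per metric plus flags naming conventions applied for
    undefined denominators."""

    dsc: float
    jsc: float
    svd: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    fpr: float
    fnr: float
    npv: float
    fdr: float
    f1: float
    mcc: float
    flags: Dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        d = {
            k: getattr(self, k)
            for k in (
                "dsc jsc svd accuracy sensitivity specificity precision "
                "fpr fnr npv fdr f1 mcc".split()
            )
        }
        return d

    CSV_FIELDS = (
        "dsc", "jsc", "svd", "accuracy", "sensitivity", "specificity",
        "precision", "fpr", "fnr", "npv", "fdr", "f1", "mcc",
    )

    def as_csv_row(self) -> str:
        """One comma-separated row in ``CSV_FIELDS`` order."""
        return ",".join(f"{getattr(self, k):.6g}" for k in self.CSV_FIELDS)


def _as_binary_vector(x) -> np.ndarray:
    arr = x.values if isinstance(x, BinaryMask) else np.asarray(x)
    flat = arr.ravel()
    if not np.isin(flat, (0, 1)).all():
        raise DomainError("labels must be 0 or 1")
    return flat.astype(np.int64)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard TP/FP/FN/TN counts for binary masks or label vectors."""
    t = _as_binary_vector(y_true)
    p = _as_binary_vector(y_pred)
    if t.shape != p.shape:
        raise ShapeError(f"shape mismatch: {t.shape} vs {p.shape}")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float, convention: float, flags: Dict[str, str], name: str) -> float:
    if den == 0:
        flags[name] = f"denominator zero; conventional value {convention}"
        return convention
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """All thirteen metrics from the counts; raises on all-zero counts."""
    if c.total == 0:
        raise DomainError("cannot compute metrics from all-zero counts")
    flags: Dict[str, str] = {}
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    dsc = _ratio(2 * tp, 2 * tp + fp + fn, 1.0, flags, "dsc")
    jsc = _ratio(tp, tp + fp + fn, 1.0, flags, "jsc")
    svd = 1.0 - dsc
    accuracy = (tp + tn) / c.total
    sensitivity = _ratio(tp, tp + fn, 1.0, flags, "sensitivity")
    specificity = _ratio(tn, tn + fp, 1.0, flags, "specificity")
    precision = _ratio(tp, tp + fp, 1.0, flags, "precision")
    fpr = _ratio(fp, fp + tn, 0.0, flags, "fpr")
    fnr = _ratio(fn, fn + tp, 0.0, flags, "fnr")
    npv = _ratio(tn, tn + fn, 1.0, flags, "npv")
    fdr = _ratio(fp, fp + tp, 0.0, flags, "fdr")
    f1 = _ratio(2 * precision * sensitivity, precision + sensitivity, 0.0, flags, "f1")
    marginals = [tp + fp, tp + fn, tn + fp, tn + fn]
    if min(marginals) == 0:
        flags["mcc"] = "a marginal is zero; conventional value 0.0"
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(float(np.prod([float(m) for m in marginals])))
    return MetricsReport(
        dsc=dsc,
        jsc=jsc,
        svd=svd,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        fpr=fpr,
        fnr=fnr,
        npv=npv,
        fdr=fdr,
        f1=f1,
        mcc=mcc,
        flags=flags,
    )


def dice(y_true, y_pred) -> float:
    """Dice similarity coefficient of two masks (1.0 for empty vs empty)."""
    return compute_metrics(confusion(y_true, y_pred)).dsc


def evaluate_masks(y_true, y_pred) -> MetricsReport:
    """Full metric report comparing a predicted mask against ground truth."""
    return compute_metrics(confusion(y_true, y_pred))
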