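"""Case-level decisions and micro-averaged evaluation.

A whole-slide case receives the *most severe* class predicted on any of
its slices ("max-voting": one invasive slice makes the case invasive).
Multi-class performance is reported with micro-averaged metrics computed
from one-vs-rest aggregates of the confusion matrix (rows = reference,
columns = prediction):

    micro_precision = TP_sum / (TP_sum + FP_sum)
    micro_recall    = TP_sum / (TP_sum + FN_sum)
    micro F         = 2 * precision * recall / (precision + recall)
    sensitivity     = TP_sum / (TP_sum + FN_sum)
    specificity     = TN_sum / (TN_sum + FP_sum)

For single-label multi-class data TP_sum is the matrix trace and
FP_sum = FN_sum = N - trace, so micro precision, recall, F and
sensitivity all coincide (with accuracy); specificity aggregates the
one-vs-rest true negatives, TN_sum = (K-2)N + trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .labels import DIAGNOSIS_CLASSES, DiagnosisClass

logger = logging.getLogger(__name__)

K = len(DIAGNOSIS_CLASSES)


def max_vote(slice_predictions: Sequence[DiagnosisClass]) -> DiagnosisClass:
    """Most severe class among the slice predictions (MMD<MIS<T1a<T1b)."""
    preds = list(slice_predictions)
    if not preds:
        raise ValueError("max_vote needs at least one slice prediction")
    return DiagnosisClass(max(int(p) for p in preds))


def majority_vote(slice_predictions: Sequence[DiagnosisClass]) -> DiagnosisClass:
    """Sensitivity-analysis variant: majority with severity tie-break."""
    preds = [DiagnosisClass(int(p)) for p in slice_predictions]
    if not preds:
        raise ValueError("majority_vote needs at least one slice prediction")
    counts = np.bincount([int(p) for p in preds], minlength=K)
    best = counts.max()
    return DiagnosisClass(int(max(np.flatnonzero(counts == best))))


@dataclass
class ConfusionMatrix:
    """K x K counts (rows reference, columns predicted) with OvR aggregates."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (K, K):
            raise ValueError(f"expected {K}x{K} counts, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def tp_sum(self) -> int:
        return int(np.trace(self.counts))

    @property
    def fp_sum(self) -> int:
        return self.n - self.tp_sum

    @property
    def fn_sum(self) -> int:
        return self.n - self.tp_sum

    @property
    def tn_sum(self) -> int:
        # per class: N - row - col + diag; summed over classes
        return (K - 2) * self.n + self.tp_sum

    def per_class(self) -> Dict[str, np.ndarray]:
        """One-vs-rest TP/FP/FN/TN per class."""
        row = self.counts.sum(axis=1)
        col = self.counts.sum(axis=0)
        tp = np.diag(self.counts)
        return {"tp": tp, "fp": col - tp, "fn": row - tp,
                "tn": self.n - row - col + tp}

    def to_frame(self) -> pd.DataFrame:
        names = [c.name for c in DIAGNOSIS_CLASSES]
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion(reference: Sequence[DiagnosisClass],
              predicted: Sequence[DiagnosisClass]) -> ConfusionMatrix:
    """Count reference x predicted pairs into a ConfusionMatrix."""
    if len(reference) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(reference)} references vs "
            f"{len(predicted)} predictions")
    ref = [int(r) for r in reference]
    pred = [int(p) for p in predicted]
    return ConfusionMatrix(
        _sk_confusion(ref, pred, labels=list(range(K))))


@dataclass
class MetricsReport:
    """Micro metrics plus per-class one-vs-rest breakdown."""

    micro_precision: float
    micro_recall: float
    micro_f: float
    sensitivity: float
    specificity: float
    per_class_f: np.ndarray
    per_class_sensitivity: np.ndarray
    per_class_specificity: np.ndarray
    n: int
    flags: List[str] = field(default_factory=list)


def _safe_div(num: float, den: float, name: str, flags: List[str]) -> float:
    if den == 0:
        flags.append(f"zero denominator in {name}; reported 0")
        logger.debug("zero denominator in %s; reporting 0", name)
        return 0.0
    return num / den


def micro_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Evaluate the micro-averaged formulas on the aggregate counts."""
    if cm.n < 1:
        raise ValueError("confusion matrix is empty")
    flags: List[str] = []
    prec = _safe_div(cm.tp_sum, cm.tp_sum + cm.fp_sum, "micro_precision", flags)
    rec = _safe_div(cm.tp_sum, cm.tp_sum + cm.fn_sum, "micro_recall", flags)
    f = _safe_div(2 * prec * rec, prec + rec, "micro_f", flags)
    sens = _safe_div(cm.tp_sum, cm.tp_sum + cm.fn_sum, "sensitivity", flags)
    spec = _safe_div(cm.tn_sum, cm.tn_sum + cm.fp_sum, "specificity", flags)

    pc = cm.per_class()
    pcf, pcs, pcsp = [], [], []
    for i in range(K):
        p = _safe_div(pc["tp"][i], pc["tp"][i] + pc["fp"][i],
                      f"precision[{i}]", flags)
        r = _safe_div(pc["tp"][i], pc["tp"][i] + pc["fn"][i],
                      f"sensitivity[{i}]", flags)
        pcf.append(_safe_div(2 * p * r, p + r, f"f[{i}]", flags))
        pcs.append(r)
        pcsp.append(_safe_div(pc["tn"][i], pc["tn"][i] + pc["fp"][i],
                              f"specificity[{i}]", flags))
    return MetricsReport(
        micro_precision=prec, micro_recall=rec, micro_f=f,
        sensitivity=sens, specificity=spec,
        per_class_f=np.array(pcf), per_class_sensitivity=np.array(pcs),
        per_class_specificity=np.array(pcsp), n=cm.n, flags=flags)


@dataclass
class SeedSummary:
    """Average/min/max/median micro F over seeds, plus mean sens/spec."""

    per_seed_f: List[float]
    mean_sensitivity: float
    mean_specificity: float

    @property
    def average(self) -> float:
        return float(np.mean(self.per_seed_f))

    @property
    def minimum(self) -> float:
        return float(np.min(self.per_seed_f))

    @property
    def maximum(self) -> float:
        return float(np.max(self.per_seed_f))

    @property
    def median(self) -> float:
        return float(np.median(self.per_seed_f))

    def to_row(self) -> Dict[str, float]:
        return {"average": self.average, "min": self.minimum,
                "max": self.maximum, "median": self.median,
                "sensitivity": self.mean_sensitivity,
                "specificity": self.mean_specificity}


def run_experiment(*args, **kwargs):
    """Multi-seed train/evaluate runner; see :func:`skindx.pipeline.run_experiment`."""
    from .pipeline import run_experiment as _impl
    return _impl(*args, **kwargs)
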