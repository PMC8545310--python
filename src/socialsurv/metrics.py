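"""Evaluation metrics: confusion-matrix scores and detection latency.

Implements accuracy, sensitivity (recall), precision, F-measure and the
geometric mean G = sqrt(TP_rate x TN_rate) of the true-positive and
true-negative rates, the standard score pair for imbalanced surveillance
data. Any metric whose denominator is zero is reported as None
(undefined), never silently as 0. Multi-class problems are reduced
one-vs-rest per class and macro-averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "compute_metrics",
    "multiclass_report",
    "detection_latency",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        """Number of positive samples."""
        return self.TP + self.FN

    @property
    def n(self) -> int:
        """Number of negative samples."""
        return self.TN + self.FP

    @property
    def tp_rate(self) -> Optional[float]:
        return self.TP / self.p if self.p > 0 else None

    @property
    def tn_rate(self) -> Optional[float]:
        return self.TN / self.n if self.n > 0 else None


@dataclass(frozen=True)
class MetricReport:
    """Scores for one (binary or one-vs-rest) confusion table; None marks
    an undefined value (zero denominator)."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    precision: Optional[float]
    f_measure: Optional[float]
    g_mean: Optional[float]


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, precision, F-measure and G-mean from counts."""
    total = c.TP + c.TN + c.FP + c.FN
    if total == 0:
        raise ValueError("empty confusion table")
    accuracy = (c.TP + c.TN) / total
    sensitivity = c.tp_rate
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    if c.tp_rate is None or c.tn_rate is None:
        g_mean = None
    else:
        g_mean = math.sqrt(c.tp_rate * c.tn_rate)
    return MetricReport(accuracy, sensitivity, precision, f_measure, g_mean)


def _macro(values: List[Optional[float]]) -> Optional[float]:
    defined = [v for v in values if v is not None]
    return sum(defined) / len(defined) if defined else None


def multiclass_report(y_true: Sequence, y_pred: Sequence
                      ) -> Dict[str, Optional[float]]:
    """One-vs-rest per class, macro-averaged (undefined classes excluded
    from each macro mean). Overall accuracy is the plain match rate."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("label arrays must be non-empty and equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    per_class = {}
    for cls in classes:
        t = y_true == cls
        p = y_pred == cls
        per_class[cls] = compute_metrics(ConfusionCounts(
            TP=int(np.sum(t & p)), TN=int(np.sum(~t & ~p)),
            FP=int(np.sum(~t & p)), FN=int(np.sum(t & ~p)),
        ))
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "sensitivity": _macro([m.sensitivity for m in per_class.values()]),
        "precision": _macro([m.precision for m in per_class.values()]),
        "f_measure": _macro([m.f_measure for m in per_class.values()]),
        "g_mean": _macro([m.g_mean for m in per_class.values()]),
    }


def detection_latency(
    detected: Sequence[Tuple[str, str, int]],
    injected: Sequence[Tuple[str, str, int]],
) -> Tuple[pd.DataFrame, Dict[str, Optional[float]]]:
    """Signed day offsets between detected and injected event onsets.

    Events are matched by (region, topic); for multiple detections of one
    pair the earliest onset counts. Offset = detected - injected onset in
    days (negative = early). Unmatched injections are recorded as misses,
    excluded from the mean offset but counted in the miss rate.
    """
    earliest: Dict[Tuple[str, str], int] = {}
    for region, topic, onset in detected:
        key = (region, topic)
        if key not in earliest or onset < earliest[key]:
            earliest[key] = onset
    rows = []
    offsets = []
    for region, topic, start in injected:
        onset = earliest.get((region, topic))
        if onset is None:
            rows.append({"region": region, "topic": topic,
                         "injected_day": start, "detected_day": None,
                         "offset_days": None, "missed": True})
        else:
            off = onset - start
            offsets.append(off)
            rows.append({"region": region, "topic": topic,
                         "injected_day": start, "detected_day": onset,
                         "offset_days": off, "missed": False})
    summary = {
        "n_injected": float(len(injected)),
        "n_detected": float(len(offsets)),
        "miss_rate": (len(injected) - len(offsets)) / len(injected)
        if injected else None,
        "mean_offset_days": float(np.mean(offsets)) if offsets else None,
    }
    return pd.DataFrame(rows), summary
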