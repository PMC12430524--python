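"""Confusion matrix and variant-level performance metrics.

The resistant class (R) is the positive class for the confusion matrix
and specificity; precision/recall/F1 are reported separately for each
class, which makes them independent of the positive-class choice.
MCC uses the standard formula with 0 substituted (and flagged) when a
denominator factor vanishes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["ConfusionMatrix", "ClassMetrics", "MetricsReport",
           "confusion_and_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with R as the positive class."""

    tp: int   # true R called R
    fp: int   # true S called R
    tn: int   # true S called S
    fn: int   # true R called S

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    specificity: float        # TN / (TN + FP), R positive
    mcc: float
    mcc_degenerate: bool      # True when a denominator factor was zero
    sensitive: ClassMetrics
    resistant: ClassMetrics

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "mcc_degenerate": self.mcc_degenerate,
            "sensitive": vars(self.sensitive).copy(),
            "resistant": vars(self.resistant).copy(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_table(self) -> pd.DataFrame:
        """One metric per row, in the conventional report layout."""
        rows = [
            ("Accuracy", self.accuracy),
            ("Specificity", self.specificity),
            ("Matthews Correlation Coefficient (MCC)", self.mcc),
            ("Sensitive: Recall", self.sensitive.recall),
            ("Sensitive: Precision", self.sensitive.precision),
            ("Sensitive: F1-Score", self.sensitive.f1),
            ("Resistant: Recall", self.resistant.recall),
            ("Resistant: Precision", self.resistant.precision),
            ("Resistant: F1-Score", self.resistant.f1),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def _prf(tp, fp, fn) -> ClassMetrics:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return ClassMetrics(precision=precision, recall=recall, f1=f1)


def confusion_and_metrics(truth, predicted):
    """Confusion matrix and metrics from variant-level S/R label vectors."""
    truth = list(truth)
    predicted = list(predicted)
    if not truth or len(truth) != len(predicted):
        raise ValueError("truth and predicted must be equal-length and nonempty")
    bad = (set(truth) | set(predicted)) - {"S", "R"}
    if bad:
        raise ValueError(f"labels outside {{S, R}}: {sorted(bad)}")
    tp = sum(t == "R" and p == "R" for t, p in zip(truth, predicted))
    fp = sum(t == "S" and p == "R" for t, p in zip(truth, predicted))
    tn = sum(t == "S" and p == "S" for t, p in zip(truth, predicted))
    fn = sum(t == "R" and p == "S" for t, p in zip(truth, predicted))
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)

    accuracy = (tp + tn) / cm.total
    specificity = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(denom)

    report = MetricsReport(
        accuracy=accuracy,
        specificity=specificity,
        mcc=mcc,
        mcc_degenerate=degenerate,
        sensitive=_prf(tp=tn, fp=fn, fn=fp),   # S as positive class
        resistant=_prf(tp=tp, fp=fp, fn=fn),   # R as positive class
    )
    return cm, report
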