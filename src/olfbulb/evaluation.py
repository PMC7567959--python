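"""Scan-level classification performance: confusion matrices and the
standard derived metrics, with PD as the positive class.

accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
specificity = TN/(TN+FP), F1 = harmonic mean of precision and recall.
Ratios with a zero denominator are reported as ``None`` and listed in
``MetricReport.undefined`` rather than coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

POSITIVE = "PD"
NEGATIVE = "NPOD"


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    accuracy: float
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    undefined: list[str] = field(default_factory=list)


def confusion(predicted, truth, positive: str = POSITIVE,
              labels: tuple[str, str] = (POSITIVE, NEGATIVE)) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel label vectors."""
    predicted, truth = list(predicted), list(truth)
    if len(predicted) != len(truth):
        raise ValueError("label vectors differ in length")
    allowed = set(labels)
    foreign = (set(predicted) | set(truth)) - allowed
    if foreign:
        raise ValueError(f"foreign labels {sorted(foreign)}; expected {labels}")
    tp = sum(1 for p, t in zip(predicted, truth) if p == positive and t == positive)
    tn = sum(1 for p, t in zip(predicted, truth) if p != positive and t != positive)
    fp = sum(1 for p, t in zip(predicted, truth) if p == positive and t != positive)
    fn = sum(1 for p, t in zip(predicted, truth) if p != positive and t == positive)
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float | None:
    if den == 0:
        undefined.append(name)
        return None
    return num / den


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be >= 0")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision", undefined)
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall", undefined)
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity", undefined)
    f1 = (f1_from_precision_recall(precision, recall)
          if precision is not None and recall is not None and precision + recall > 0
          else None)
    if f1 is None and "f1" not in undefined:
        undefined.append("f1")
    return MetricReport(accuracy=(cm.tp + cm.tn) / cm.total, precision=precision,
                        recall=recall, specificity=specificity, f1=f1,
                        undefined=undefined)


def scan_table_report(scan_table) -> tuple[MetricReport, dict[str, int]]:
    """Metrics plus per-class misclassification counts from a scan table.

    ``scan_table`` is a DataFrame with columns ``true`` and ``predicted``
    (labels in {PD, NPOD}); returns the metric report and a dict of
    misdiagnosed scan counts per true class, including the total.
    """
    truth = list(scan_table["true"])
    pred = list(scan_table["predicted"])
    cm = confusion(pred, truth)
    errors = {
        POSITIVE: int(sum(1 for p, t in zip(pred, truth) if t == POSITIVE and p != t)),
        NEGATIVE: int(sum(1 for p, t in zip(pred, truth) if t == NEGATIVE and p != t)),
    }
    errors["total"] = errors[POSITIVE] + errors[NEGATIVE]
    return compute_metrics(cm), errors


def majority_vote_by_subject(scan_table):
    """Optional subject-level aggregation: per-subject majority vote over
    scan predictions (ties broken toward the positive class)."""
    out = []
    for sid, grp in scan_table.groupby("subject_id"):
        n_pos = int((grp["predicted"] == POSITIVE).sum())
        pred = POSITIVE if n_pos * 2 >= len(grp) else NEGATIVE
        out.append({"subject_id": sid, "true": grp["true"].iloc[0], "predicted": pred})
    import pandas as pd

    return pd.DataFrame(out)
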