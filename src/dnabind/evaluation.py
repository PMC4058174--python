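"""Confusion-matrix bookkeeping and binary-classification metrics.

Conventions: the positive class is DNA-binding (+1). Sensitivity,
specificity and accuracy are held as percentages; precision, recall and
F1 as fractions (F1 is also commonly tabulated as a percentage — see
:meth:`MetricsReport.format_text`); MCC lies in [-1, 1]. A metric whose
denominator is zero is reported as 0 and the metric name is recorded in
``degenerate``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from dnabind.ensemble import EnsembleModel, TrainingSet


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived metrics SE/SP/ACC/MCC/P/R/F1."""

    tp: int
    fp: int
    tn: int
    fn: int
    se: float   # sensitivity (recall), percent
    sp: float   # specificity, percent
    acc: float  # accuracy, percent
    mcc: float
    precision: float
    recall: float
    f1: float
    degenerate: tuple[str, ...] = field(default=())

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "SE": self.se, "SP": self.sp, "ACC": self.acc, "MCC": self.mcc,
            "P": self.precision, "R": self.recall, "F1": self.f1,
            "degenerate": list(self.degenerate),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def format_text(self) -> str:
        """Human-readable report: percentages to 2 decimals, MCC to 2."""
        lines = [
            f"TP={self.tp}  FP={self.fp}  TN={self.tn}  FN={self.fn}",
            f"ACC = {self.acc:.2f}%",
            f"MCC = {self.mcc:.2f}",
            f"SE  = {self.se:.2f}%",
            f"SP  = {self.sp:.2f}%",
            f"F1  = {100 * self.f1:.2f}%",
            f"P   = {self.precision:.4f}",
            f"R   = {self.recall:.4f}",
        ]
        if self.degenerate:
            lines.append("degenerate: " + ", ".join(self.degenerate))
        return "\n".join(lines)


def confusion(
    labels_true: Sequence[int], labels_pred: Sequence[int]
) -> tuple[int, int, int, int]:
    """Counts (TP, FP, TN, FN) from aligned {-1, +1} label sequences.

    TP: positives classified positive; FP: negatives classified
    positive; TN: negatives classified negative; FN: positives
    classified negative.
    """
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    if len(t) == 0:
        raise ValueError("need at least one label pair")
    for arr, name in ((t, "true"), (p, "predicted")):
        if not np.all(np.isin(arr, (-1, 1))):
            raise ValueError(f"{name} labels must take values in {{-1, +1}}")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == -1) & (p == 1)))
    tn = int(np.sum((t == -1) & (p == -1)))
    fn = int(np.sum((t == 1) & (p == -1)))
    return tp, fp, tn, fn


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Derive SE, SP, ACC, MCC, P, R and F1 from confusion counts."""
    for value, name in ((tp, "TP"), (fp, "FP"), (tn, "TN"), (fn, "FN")):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    total = tp + fp + tn + fn
    if total < 1:
        raise ValueError("need at least one evaluated sample")
    flags: list[str] = []
    se = 100.0 * _ratio(tp, tp + fn, "SE", flags)
    sp = 100.0 * _ratio(tn, tn + fp, "SP", flags)
    acc = 100.0 * (tp + tn) / total
    mcc_den = math.sqrt(
        float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    )
    if mcc_den == 0:
        flags.append("MCC")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    precision = _ratio(tp, tp + fp, "P", flags)
    recall = _ratio(tp, tp + fn, "R", flags)
    if precision + recall == 0:
        flags.append("F1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        se=se, sp=sp, acc=acc, mcc=mcc,
        precision=precision, recall=recall, f1=f1,
        degenerate=tuple(flags),
    )


def metrics_from_labels(
    labels_true: Sequence[int], labels_pred: Sequence[int]
) -> MetricsReport:
    """Convenience: confusion counts then metrics in one step."""
    return metrics(*confusion(labels_true, labels_pred))


def evaluate_model(
    model: EnsembleModel, test: TrainingSet
) -> tuple[MetricsReport, pd.DataFrame]:
    """Predict on a labelled test set and report metrics.

    Returns the metrics report and a per-record prediction table with
    columns ``id``, ``true``, ``pred``, ``score``.
    """
    pred, scores = model.predict(test.X)
    report = metrics_from_labels(test.y, pred)
    ids = test.ids if test.ids is not None else [str(i) for i in range(len(test))]
    table = pd.DataFrame(
        {"id": ids, "true": test.y, "pred": pred, "score": scores}
    )
    return report, table
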