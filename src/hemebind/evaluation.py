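"""Confusion counting and the five binding-residue evaluation measures.

Recall, precision, accuracy and F1 are reported as percentages; the
Matthews correlation coefficient (MCC) is a real number in [-1, 1].  When
a denominator factor is zero the affected metric is defined as 0 — real
benchmark runs never hit these cases, but degenerate toy inputs can.

Fold-averaged metrics (the cross-validation convention used throughout)
are unweighted means over folds and generally differ from metrics pooled
over all residues; reports label which of the two they show.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from math import sqrt

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvaluationError",
    "confusion",
    "compute_metrics",
    "fold_average",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.total == 0:
            raise EvaluationError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class Metrics:
    recall: float     # percent
    precision: float  # percent
    accuracy: float   # percent
    f1: float         # percent
    mcc: float        # in [-1, 1]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def tsv_row(self) -> str:
        return "\t".join(
            f"{v:.2f}" for v in (self.recall, self.precision, self.accuracy, self.f1)
        ) + f"\t{self.mcc:.3f}"


def confusion(pred, truth) -> ConfusionCounts:
    """Exact 2x2 tally of binary predictions against binary truth."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise EvaluationError("prediction and truth must cover the same residues")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Recall, precision, accuracy, F1 (percent) and MCC from counts."""
    recall = _ratio(c.tp, c.tp + c.fn)
    precision = _ratio(c.tp, c.tp + c.fp)
    accuracy = (c.tp + c.tn) / c.total
    f1 = _ratio(2 * precision * recall, precision + recall)
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (c.tp * c.tn - c.fp * c.fn) / sqrt(denom) if denom > 0 else 0.0
    return Metrics(
        recall=100.0 * recall,
        precision=100.0 * precision,
        accuracy=100.0 * accuracy,
        f1=100.0 * f1,
        mcc=mcc,
    )


def fold_average(per_fold: list[Metrics]) -> Metrics:
    """Unweighted arithmetic mean of each metric across folds."""
    if not per_fold:
        raise EvaluationError("no folds to average")
    return Metrics(
        recall=float(np.mean([m.recall for m in per_fold])),
        precision=float(np.mean([m.precision for m in per_fold])),
        accuracy=float(np.mean([m.accuracy for m in per_fold])),
        f1=float(np.mean([m.f1 for m in per_fold])),
        mcc=float(np.mean([m.mcc for m in per_fold])),
    )
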