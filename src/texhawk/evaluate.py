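"""Confusion-matrix bookkeeping and the classification report.

The positive class is the diseased ("malignant") class, label 1.  Besides
accuracy and sensitivity the report carries the TN/(TN+FP) ratio twice: once
as ``specificity`` (its textbook name) and once as ``paper_precision`` — some
published pipelines report this specificity kernel under the name
"precision", so both are exposed alongside the standard TP/(TP+FP) precision
to keep comparisons unambiguous.  Metrics with a zero denominator are
``None`` (undefined), never silently 0.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["ConfusionCounts", "ClassificationReport", "confusion_counts", "classification_metrics"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationReport:
    """Percent-scale metrics plus the counts they derive from."""

    counts: ConfusionCounts
    accuracy: float | None
    sensitivity: float | None
    precision: float | None
    specificity: float | None
    paper_precision: float | None

    def to_dict(self) -> dict:
        return {
            "counts": asdict(self.counts),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "specificity": self.specificity,
            "paper_precision": self.paper_precision,
        }


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with positive class = 1."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        logger.warning("metric %s undefined: zero denominator", name)
        return None
    return 100.0 * num / den


def classification_metrics(counts: ConfusionCounts) -> ClassificationReport:
    """Percent metrics from counts.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN), precision =
    TP/(TP+FP); specificity = TN/(TN+FP) is also reported under the alias
    ``paper_precision``.
    """
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    return ClassificationReport(
        counts=counts,
        accuracy=_ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        precision=_ratio(counts.tp, counts.tp + counts.fp, "precision"),
        specificity=spec,
        paper_precision=spec,
    )
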