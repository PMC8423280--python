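"""Confusion-matrix metrics, ROC/AUC, and the per-learner metric vector.

Accuracy, precision, recall and F1 follow the standard confusion-matrix
definitions

    Acc = (TP + TN) / (TP + FP + TN + FN)
    Pre = TP / (TP + FP)
    Rec = TP / (TP + FN)
    F1  = 2 / (1/Pre + 1/Rec)

AUC is computed in its Mann–Whitney form: the probability that a random
positive sample outranks a random negative one, ties counted half.  The
returned ROC curve's trapezoidal area equals this rank statistic to
machine precision, which the test suite asserts.

Zero denominators (a learner that never predicts the positive class, a
fold with no positives) yield a metric of 0 plus an entry in the
``zero_division`` flag set rather than an exception, so cross-validated
evaluation never aborts on a degenerate learner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import AlignmentError, UndefinedAUCError, ValidationError
from .data_model import ClassCatalog, LabelVector, ProbabilityTable

#: Averaging modes for precision/recall/F1 over the two classes.
AVERAGING_MODES = ("weighted", "positive")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies for one positive-class orientation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassificationReport:
    """Accuracy/precision/recall/F1 plus zero-division flags."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    zero_division: frozenset[str] = frozenset()


@dataclass(frozen=True)
class MetricVector:
    """The four-metric array A = (precision, recall, F1, AUC) that drives
    ensemble weight computation, tagged with the averaging mode used."""

    precision: float
    recall: float
    f1: float
    auc: float
    mode: str = "weighted"

    def __post_init__(self) -> None:
        for label, v in (
            ("precision", self.precision),
            ("recall", self.recall),
            ("f1", self.f1),
            ("auc", self.auc),
        ):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{label}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.precision, self.recall, self.f1, self.auc])


@dataclass(frozen=True)
class RocCurve:
    """Operating points of the ROC curve, from (0,0) to (1,1).

    ``thresholds[i]`` is the score at/above which a sample is called
    positive at point ``i``; the first point uses +inf (call nothing).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def trapezoid_area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def confusion_counts(
    labels: LabelVector, predictions: list[str] | tuple[str, ...], positive: str
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN of ``predictions`` against ``labels``.

    A true positive is a positive-class sample predicted positive; the
    other three cells follow by crossing actual with predicted class.
    """
    if len(predictions) != len(labels):
        raise AlignmentError(
            f"{len(predictions)} predictions for {len(labels)} labels"
        )
    labels.catalog.index(positive)  # membership check
    y = np.asarray(labels.labels) == positive
    p = np.asarray(predictions) == positive
    return ConfusionCounts(
        tp=int(np.sum(y & p)),
        fp=int(np.sum(~y & p)),
        tn=int(np.sum(~y & ~p)),
        fn=int(np.sum(y & ~p)),
    )


def classification_metrics(counts: ConfusionCounts) -> ClassificationReport:
    """Accuracy, precision, recall and F1 from confusion tallies."""
    if counts.total == 0:
        raise ValidationError("cannot compute metrics on zero samples")
    flags: set[str] = set()

    def safe(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.add(name)
            return 0.0
        return num / den

    acc = (counts.tp + counts.tn) / counts.total
    pre = safe(counts.tp, counts.tp + counts.fp, "precision")
    rec = safe(counts.tp, counts.tp + counts.fn, "recall")
    if pre + rec == 0.0:
        flags.add("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * pre * rec / (pre + rec)
    return ClassificationReport(acc, pre, rec, f1, frozenset(flags))


def auc_score(
    labels: LabelVector,
    positive_scores: np.ndarray | list[float],
    positive: str | None = None,
) -> tuple[float, RocCurve]:
    """Mann–Whitney AUC of ``positive_scores`` plus the ROC curve.

    Returns the probability that a uniformly random positive sample
    scores strictly above a uniformly random negative one, with ties
    credited one half.  Requires both classes present.
    """
    positive = positive if positive is not None else labels.catalog.positive
    scores = np.asarray(positive_scores, dtype=float)
    if scores.shape != (len(labels),):
        raise AlignmentError(
            f"{scores.shape[0] if scores.ndim else 0} scores for "
            f"{len(labels)} labels"
        )
    pos = np.asarray(labels.labels) == positive
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined: labels contain a single class "
            f"({n_pos} positive / {n_neg} negative)"
        )
    ranks = rankdata(scores)  # mid-ranks for ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    return auc, _roc_curve(scores, pos, n_pos, n_neg)


def _roc_curve(
    scores: np.ndarray, pos: np.ndarray, n_pos: int, n_neg: int
) -> RocCurve:
    # Sweep distinct score thresholds high-to-low; ties grouped so the
    # trapezoid area reproduces the mid-rank statistic exactly.
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    is_pos = pos[order].astype(float)
    boundary = np.flatnonzero(np.diff(s) != 0)
    last = np.concatenate([boundary, [len(s) - 1]])
    cum_tp = np.cumsum(is_pos)[last]
    cum_fp = np.cumsum(1.0 - is_pos)[last]
    tpr = np.concatenate([[0.0], cum_tp / n_pos])
    fpr = np.concatenate([[0.0], cum_fp / n_neg])
    thresholds = np.concatenate([[np.inf], s[last]])
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def predictions_argmax(table: ProbabilityTable) -> list[str]:
    """Per-row argmax class; ties resolve to the lowest catalog index."""
    idx = np.argmax(table.probabilities, axis=1)
    return [table.catalog.classes[i] for i in idx]


def metric_vector(
    labels: LabelVector,
    table: ProbabilityTable,
    positive: str | None = None,
    mode: str = "weighted",
) -> MetricVector:
    """Assemble the metric array A = (pre, rec, f1, auc) for one learner.

    Predictions are the per-row argmax of the table.  Precision, recall
    and F1 are computed either for the positive class only
    (``mode="positive"``) or support-weighted across all classes
    (``mode="weighted"``, the default).  AUC always uses the
    positive-class probability column.
    """
    if mode not in AVERAGING_MODES:
        raise ValidationError(f"unknown averaging mode {mode!r}")
    catalog = table.catalog
    positive = positive if positive is not None else catalog.positive
    preds = predictions_argmax(table)
    auc, _ = auc_score(labels, table.positive_scores(), positive)

    if mode == "positive":
        rep = classification_metrics(confusion_counts(labels, preds, positive))
        return MetricVector(rep.precision, rep.recall, rep.f1, auc, mode)

    y = np.asarray(labels.labels)
    total = len(labels)
    pre = rec = f1 = 0.0
    for cls in catalog.classes:
        support = int(np.sum(y == cls))
        if support == 0:
            continue
        rep = classification_metrics(confusion_counts(labels, preds, cls))
        w = support / total
        pre += w * rep.precision
        rec += w * rep.recall
        f1 += w * rep.f1
    return MetricVector(pre, rec, f1, auc, mode)


def accuracy_of(labels: LabelVector, predictions: list[str]) -> float:
    """Fraction of predictions equal to the true label."""
    if len(predictions) != len(labels):
        raise AlignmentError("predictions and labels differ in length")
    return float(np.mean(np.asarray(predictions) == np.asarray(labels.labels)))


__all__ = [
    "AVERAGING_MODES",
    "ConfusionCounts",
    "ClassificationReport",
    "MetricVector",
    "RocCurve",
    "confusion_counts",
    "classification_metrics",
    "auc_score",
    "metric_vector",
    "predictions_argmax",
    "accuracy_of",
]
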