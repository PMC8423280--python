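"""Stratified k-fold evaluation of base learners and fusion methods.

The protocol mirrors the evaluation loop of the fusion benchmark: for
each fold, ensemble weights are fitted on the out-of-fold (training)
samples and the fused model is scored on the held-in (test) samples, so
no test sample's label ever influences the weights used to predict it.
Per-fold rows of (accuracy, precision, recall, f1, auc) are collected
for every base learner and every requested fusion method, and
aggregated as mean ± standard deviation.

Base CNN training is outside this package's scope: the protocol
consumes precomputed per-sample probability scores from each learner
over all samples and re-fits only the fusion weights per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ClassifierBundle, LabelVector
from .errors import (
    AlignmentError,
    SchemaError,
    StratificationError,
    UndefinedAUCError,
    ValidationError,
)
from .fusion import (
    FusionSpec,
    WeightVector,
    accuracy_weights,
    fit_weights,
    fuse_weighted,
    majority_vote,
    predict_argmax,
    uniform_weights,
)
from .metrics import (
    ConfusionCounts,
    auc_score,
    classification_metrics,
    confusion_counts,
    metric_vector,
    predictions_argmax,
)

METRIC_COLUMNS = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (1..k) per sample, produced by stratified partitioning."""

    sample_ids: tuple[str, ...]
    folds: np.ndarray  # int, values in 1..k
    k: int
    seed: int

    def __post_init__(self) -> None:
        folds = np.asarray(self.folds, dtype=int)
        if folds.shape != (len(self.sample_ids),):
            raise AlignmentError("fold array does not match sample_ids")
        if folds.size and (folds.min() < 1 or folds.max() > self.k):
            raise ValidationError("fold indices must lie in 1..k")
        object.__setattr__(self, "folds", folds)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds != fold)


def stratified_folds(
    labels: LabelVector, k: int, seed: int, stratify: bool = True
) -> FoldAssignment:
    """Partition samples into k folds, preserving class proportions.

    Within each class, samples are shuffled (deterministically from
    ``seed``) and dealt round-robin, so per-fold class counts deviate
    from perfect stratification by at most one.  With ``stratify=False``
    samples are dealt round-robin after a global shuffle.
    """
    if k < 2:
        raise StratificationError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    n = len(labels)
    folds = np.zeros(n, dtype=int)
    y = np.asarray(labels.labels)
    if stratify:
        for cls in labels.catalog.classes:
            idx = np.flatnonzero(y == cls)
            if idx.size == 0:
                continue
            if idx.size < k:
                raise StratificationError(
                    f"class {cls!r} has {idx.size} samples, fewer than k={k}"
                )
            rng.shuffle(idx)
            folds[idx] = (np.arange(idx.size) % k) + 1
    else:
        idx = rng.permutation(n)
        folds[idx] = (np.arange(n) % k) + 1
    return FoldAssignment(labels.sample_ids, folds, k, seed)


def read_folds(path: str | Path, labels: LabelVector) -> FoldAssignment:
    """Read a ``sample_id,fold`` CSV aligned to a label vector."""
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str})
    for col in ("sample_id", "fold"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    mapping = dict(zip(df["sample_id"], df["fold"].astype(int)))
    missing = [s for s in labels.sample_ids if s not in mapping]
    if missing:
        raise AlignmentError(f"{path}: no fold for samples {missing[:10]}")
    folds = np.array([mapping[s] for s in labels.sample_ids], dtype=int)
    return FoldAssignment(labels.sample_ids, folds, int(folds.max()), seed=-1)


def write_folds(
    assignment: FoldAssignment, path: str | Path, header_comment: str | None = None
) -> None:
    df = pd.DataFrame(
        {"sample_id": list(assignment.sample_ids), "fold": assignment.folds}
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


@dataclass
class FoldReport:
    """Per-fold metric rows, mean±std aggregate, and fold artifacts.

    ``per_fold`` has columns (method, fold, accuracy, precision, recall,
    f1, auc); ``summary`` one row per method with ``mean_<m>`` and
    ``std_<m>`` columns.  ``std_convention`` records whether the std is
    population (ddof=0) or sample (ddof=1).  ``weights`` maps
    (fold, method) to the weight vector fitted on that fold's training
    portion; ``confusions`` maps (method, fold) to test-fold confusion
    counts; ``oof_predictions`` holds each sample's out-of-fold
    predicted class per method.
    """

    per_fold: pd.DataFrame
    summary: pd.DataFrame
    std_convention: str
    k: int
    weights: dict[tuple[int, str], WeightVector] = field(default_factory=dict)
    confusions: dict[tuple[str, int], ConfusionCounts] = field(default_factory=dict)
    oof_predictions: pd.DataFrame | None = None
    oof_scores: pd.DataFrame | None = None


def _evaluate(labels, preds, scores, positive, mode):
    """One (accuracy, precision, recall, f1, auc) row plus confusion."""
    counts = confusion_counts(labels, preds, positive)
    rep = classification_metrics(counts)
    auc, _ = auc_score(labels, scores, positive)
    if mode == "positive":
        row = (rep.accuracy, rep.precision, rep.recall, rep.f1, auc)
    else:
        # support-weighted P/R/F1 from per-class confusions
        y = np.asarray(labels.labels)
        pre = rec = f1 = 0.0
        for cls in labels.catalog.classes:
            support = int(np.sum(y == cls))
            if support == 0:
                continue
            r = classification_metrics(confusion_counts(labels, preds, cls))
            w = support / len(labels)
            pre += w * r.precision
            rec += w * r.recall
            f1 += w * r.f1
        row = (rep.accuracy, pre, rec, f1, auc)
    return row, counts


def run_protocol(
    bundle: ClassifierBundle,
    labels: LabelVector,
    folds: FoldAssignment,
    methods: Sequence[FusionSpec],
    positive: str | None = None,
    mode: str = "weighted",
    std_convention: str = "population",
    include_base: bool = True,
) -> FoldReport:
    """Evaluate base learners and fusion methods across all folds.

    For every fold, weighted methods are fitted on the training portion
    and all methods are evaluated on the test portion.  Raises
    :class:`UndefinedAUCError` naming the fold if a training portion is
    single-class (weights would be unfittable).
    """
    if bundle.sample_ids != labels.sample_ids:
        raise AlignmentError("bundle and labels sample order differ")
    if folds.sample_ids != labels.sample_ids:
        raise AlignmentError("folds and labels sample order differ")
    if std_convention not in ("population", "sample"):
        raise ValidationError(f"unknown std convention {std_convention!r}")
    positive = positive if positive is not None else labels.catalog.positive
    ddof = 0 if std_convention == "population" else 1

    rows = []
    weights_by_fold: dict[tuple[int, str], WeightVector] = {}
    confusions: dict[tuple[str, int], ConfusionCounts] = {}
    oof: dict[str, dict[str, str]] = {}
    oof_s: dict[str, dict[str, float]] = {}

    for fold in range(1, folds.k + 1):
        train_idx = folds.train_indices(fold)
        test_idx = folds.test_indices(fold)
        train_labels = labels.subset(train_idx)
        test_labels = labels.subset(test_idx)
        if len(set(train_labels.labels)) < 2:
            raise UndefinedAUCError(
                f"fold {fold}: training portion contains a single class"
            )
        train_bundle = bundle.subset(train_idx)
        test_bundle = bundle.subset(test_idx)

        def record(method: str, preds, scores):
            row, counts = _evaluate(test_labels, preds, scores, positive, mode)
            rows.append((method, fold, *row))
            confusions[(method, fold)] = counts
            store = oof.setdefault(method, {})
            score_store = oof_s.setdefault(method, {})
            for sid, p, s in zip(test_labels.sample_ids, preds, scores):
                store[sid] = p
                score_store[sid] = float(s)

        if include_base:
            for table in test_bundle:
                record(
                    table.name,
                    predictions_argmax(table),
                    table.positive_scores(),
                )

        for spec in methods:
            if spec.method == "tanh":
                wv = fit_weights(train_bundle, train_labels, positive, mode)
            elif spec.method == "accuracy":
                wv = accuracy_weights(train_bundle, train_labels)
            elif spec.method in ("average", "max"):
                wv = uniform_weights(train_bundle)
            else:  # majority
                wv = None
            if wv is not None:
                weights_by_fold[(fold, spec.method)] = wv

            if spec.method == "majority":
                preds = majority_vote(test_bundle)
                # the voting rule's only ranking is the positive vote share
                stacked = test_bundle.stacked()
                hard = np.argmax(stacked, axis=2)
                pos_idx = labels.catalog.index(positive)
                scores = (hard == pos_idx).mean(axis=0)
            else:
                fused = fuse_weighted(test_bundle, wv, name=spec.method)
                preds = predict_argmax(fused)
                scores = fused.positive_scores()
            record(spec.method, preds, scores)

    per_fold = pd.DataFrame(
        rows, columns=["method", "fold", *METRIC_COLUMNS]
    )
    grouped = per_fold.groupby("method", sort=False)
    summary = pd.concat(
        [
            grouped[list(METRIC_COLUMNS)].mean().add_prefix("mean_"),
            grouped[list(METRIC_COLUMNS)].std(ddof=ddof).add_prefix("std_"),
        ],
        axis=1,
    ).reset_index()

    oof_df = pd.DataFrame(
        {m: pd.Series(v) for m, v in oof.items()}
    ).reindex(list(labels.sample_ids))
    oof_df.index.name = "sample_id"
    oof_s_df = pd.DataFrame(
        {m: pd.Series(v) for m, v in oof_s.items()}
    ).reindex(list(labels.sample_ids))
    oof_s_df.index.name = "sample_id"

    return FoldReport(
        per_fold=per_fold,
        summary=summary,
        std_convention=std_convention,
        k=folds.k,
        weights=weights_by_fold,
        confusions=confusions,
        oof_predictions=oof_df,
        oof_scores=oof_s_df,
    )


__all__ = [
    "METRIC_COLUMNS",
    "FoldAssignment",
    "FoldReport",
    "stratified_folds",
    "read_folds",
    "write_folds",
    "run_protocol",
]
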