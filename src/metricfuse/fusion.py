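"""Decision fusion: metric-fused weights and probability-level ensembles.

The central idea: each base learner i earns a weight

    w_i = tanh(pre_i) + tanh(rec_i) + tanh(f1_i) + tanh(auc_i)

— the sum of hyperbolic tangents of its precision, recall, F1 and AUC
measured on a weight-fitting split.  Because each metric lives in
[0, 1] and tanh is increasing and concave there, each term lies in
[0, tanh(1) ≈ 0.762]: strong metrics are rewarded with near-maximal
contribution while weak ones are progressively discounted.  The fused
probability for sample j is the weight-normalized convex combination

    ens_j = Σ_i w_i p_j^(i) / Σ_i w_i

and the predicted class is the argmax of the fused row.

Four comparison ensembles are provided: uniform averaging, per-class
probability summation ("maximum probability"), majority voting, and
accuracy-only weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import ClassifierBundle, LabelVector, ProbabilityTable
from .errors import (
    DegenerateWeightsError,
    FusionSpecError,
    ValidationError,
)
from .metrics import (
    MetricVector,
    accuracy_of,
    metric_vector,
    predictions_argmax,
)

#: Recognized fusion method tags.
FUSION_METHODS = ("tanh", "accuracy", "average", "max", "majority")

#: Upper bound of one metric's tanh contribution (metric domain is [0, 1]).
MAX_CONTRIBUTION = math.tanh(1.0)

#: Upper bound of a tanh-fused weight: four metrics at their maximum.
MAX_WEIGHT = 4.0 * MAX_CONTRIBUTION


@dataclass(frozen=True)
class WeightVector:
    """One non-negative weight per base learner plus its provenance."""

    weights: dict[str, float]
    provenance: str  # tanh-fused | accuracy-only | uniform | manual

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("weight vector must be non-empty")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("weights must be non-negative")
        if all(w == 0 for w in self.weights.values()):
            raise DegenerateWeightsError("all weights are zero")
        if self.provenance == "tanh-fused" and any(
            w > MAX_WEIGHT + 1e-12 for w in self.weights.values()
        ):
            raise ValidationError(
                f"tanh-fused weight exceeds 4*tanh(1) = {MAX_WEIGHT:.6f}"
            )

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.weights]
        if missing:
            raise ValidationError(f"no weight for classifiers {missing}")
        return np.array([self.weights[n] for n in names], dtype=float)


@dataclass(frozen=True)
class FusionSpec:
    """Which fusion rule to apply and where its weights are fitted.

    ``fit_source`` is a free-text tag naming the split whose scores feed
    metric computation (e.g. ``"train"`` or ``"validation"``); it is
    required for the two weighted methods and meaningless for the rest.
    """

    method: str
    fit_source: str | None = None

    def __post_init__(self) -> None:
        if self.method not in FUSION_METHODS:
            raise FusionSpecError(
                f"unknown fusion method {self.method!r}; "
                f"expected one of {FUSION_METHODS}"
            )

    @property
    def needs_fitting(self) -> bool:
        return self.method in ("tanh", "accuracy")


def tanh_contribution(x: float) -> float:
    """One metric's contribution tanh(x) to a learner's weight.

    Defined on the metric domain [0, 1], where it increases from 0 to
    tanh(1) ≈ 0.762.
    """
    if not (0.0 <= x <= 1.0):
        raise ValidationError(f"metric value {x} outside [0, 1]")
    return math.tanh(x)


def learner_weight(metrics: MetricVector) -> float:
    """Tanh-fused weight of one learner: Σ tanh(metric) over the four
    metrics (precision, recall, F1, AUC)."""
    return sum(tanh_contribution(float(x)) for x in metrics.as_array())


def fit_weights(
    bundle: ClassifierBundle,
    labels: LabelVector,
    positive: str | None = None,
    mode: str = "weighted",
) -> WeightVector:
    """Fit one tanh-fused weight per classifier from its metric vector.

    The labels and scores passed here define the weight-fitting split;
    callers are responsible for keeping that split disjoint from the
    samples the fused model is evaluated on.
    """
    weights = {
        t.name: learner_weight(metric_vector(labels, t, positive, mode))
        for t in bundle
    }
    return WeightVector(weights, provenance="tanh-fused")


def accuracy_weights(
    bundle: ClassifierBundle, labels: LabelVector
) -> WeightVector:
    """Accuracy-only weights: the comparison scheme that weights each
    learner by its plain accuracy on the fitting split."""
    weights = {
        t.name: accuracy_of(labels, predictions_argmax(t)) for t in bundle
    }
    return WeightVector(weights, provenance="accuracy-only")


def uniform_weights(bundle: ClassifierBundle) -> WeightVector:
    return WeightVector({t.name: 1.0 for t in bundle}, provenance="uniform")


def fuse_weighted(
    bundle: ClassifierBundle,
    weights: WeightVector | Mapping[str, float],
    name: str = "ensemble",
) -> ProbabilityTable:
    """Weight-normalized convex combination of the base probability rows.

    The output is invariant to rescaling all weights by a positive
    constant, and every output row sums to 1 whenever the inputs do.
    """
    if not isinstance(weights, WeightVector):
        weights = WeightVector(dict(weights), provenance="manual")
    extra = set(weights.weights) - set(bundle.names)
    if extra:
        raise ValidationError(f"weights for unknown classifiers: {sorted(extra)}")
    w = weights.as_array(bundle.names)
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError("weights sum to zero")
    fused = np.tensordot(w / total, bundle.stacked(), axes=(0, 0))
    return ProbabilityTable(name, bundle.sample_ids, fused, bundle.catalog)


def predict_argmax(table: ProbabilityTable) -> list[str]:
    """Predicted class per row: position of the maximal fused probability,
    ties resolved to the lowest catalog index."""
    return predictions_argmax(table)


def majority_vote(bundle: ClassifierBundle) -> list[str]:
    """Plurality vote over per-classifier argmax predictions.

    Vote ties are broken by the highest mean probability among the tied
    classes, then by the lowest catalog index.  (With three learners on
    a binary task ties cannot occur; the rule makes the operation total
    for any K.)
    """
    stacked = bundle.stacked()  # (K, n, C)
    k, n, n_classes = stacked.shape
    votes = np.zeros((n, n_classes), dtype=int)
    per_clf = np.argmax(stacked, axis=2)  # (K, n)
    for ci in range(k):
        votes[np.arange(n), per_clf[ci]] += 1
    mean_probs = stacked.mean(axis=0)  # (n, C)
    out = []
    classes = bundle.catalog.classes
    for j in range(n):
        top = votes[j].max()
        tied = np.flatnonzero(votes[j] == top)
        if len(tied) == 1:
            out.append(classes[tied[0]])
            continue
        best = tied[np.argmax(mean_probs[j, tied])]  # argmax → lowest index on ties
        out.append(classes[best])
    return out


def fuse_baseline(
    bundle: ClassifierBundle,
    spec: FusionSpec,
    labels_for_fitting: LabelVector | None = None,
) -> ProbabilityTable | list[str]:
    """Apply one of the comparison ensembles of the benchmark suite.

    * ``average`` — uniform-weight convex combination.
    * ``max`` — per-class probability sum over learners, argmax; the
      returned table is the sum divided by K so it remains a valid
      probability table (predictions are unchanged by the scaling).
    * ``majority`` — plurality vote over per-learner argmax predictions;
      returns the predicted-class list.
    * ``accuracy`` — convex combination weighted by per-learner accuracy
      on ``labels_for_fitting`` (required for this method only).
    * ``tanh`` — handled by :func:`fit_weights` + :func:`fuse_weighted`;
      accepted here for completeness, fitted on ``labels_for_fitting``.
    """
    if spec.needs_fitting and labels_for_fitting is None:
        raise FusionSpecError(
            f"method {spec.method!r} requires labels_for_fitting"
        )
    if spec.method == "average":
        return fuse_weighted(bundle, uniform_weights(bundle), name="average")
    if spec.method == "max":
        # per-class sum == K * uniform mean; normalize by K for a valid table
        return fuse_weighted(bundle, uniform_weights(bundle), name="max")
    if spec.method == "majority":
        return majority_vote(bundle)
    if spec.method == "accuracy":
        assert labels_for_fitting is not None
        return fuse_weighted(
            bundle, accuracy_weights(bundle, labels_for_fitting), name="accuracy"
        )
    if spec.method == "tanh":
        assert labels_for_fitting is not None
        return fuse_weighted(
            bundle, fit_weights(bundle, labels_for_fitting), name="tanh"
        )
    raise FusionSpecError(f"unknown fusion method {spec.method!r}")


__all__ = [
    "FUSION_METHODS",
    "MAX_CONTRIBUTION",
    "MAX_WEIGHT",
    "WeightVector",
    "FusionSpec",
    "tanh_contribution",
    "learner_weight",
    "fit_weights",
    "accuracy_weights",
    "uniform_weights",
    "fuse_weighted",
    "predict_argmax",
    "majority_vote",
    "fuse_baseline",
]
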