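"""Correlated base-learner score simulator with controllable AUC.

The generator emulates the probability outputs of K binary classifiers
applied to the same samples, without any images or trained networks.
It uses an equal-variance binormal latent model:

* each sample j draws a shared standard-normal factor z_j and each
  classifier i an idiosyncratic normal noise e_ij; the latent score is
  sqrt(rho)·z_j + sqrt(1−rho)·e_ij, so any two classifiers' latent
  scores correlate at rho while each remains standard normal;
* positive samples receive a mean shift d_i = sqrt(2)·Φ⁻¹(AUC_i) on
  classifier i's latent score — under the equal-variance binormal model
  the AUC is exactly Φ(d/sqrt(2)), so the shift targets the requested
  AUC analytically;
* latent scores map to positive-class probabilities through the
  standard logistic (scale 1).  The map is strictly increasing, so it
  changes calibration but not AUC.

Defaults mirror a class-imbalanced chest-radiograph screening setting:
~73% positive prevalence and three moderately correlated learners of
AUC 0.85–0.90.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtri

from .data_model import ClassCatalog, ClassifierBundle, LabelVector, ProbabilityTable
from .errors import ValidationError

DEFAULT_CATALOG = ClassCatalog(("Normal", "Pneumonia"), positive="Pneumonia")


@dataclass(frozen=True)
class SimulatorConfig:
    """Conditions of one simulated score-generation experiment.

    Parameters
    ----------
    n : number of samples (≥ 2).
    prevalence : positive-class probability per sample, in (0, 1).
    aucs : target AUC per classifier, each in (0.5, 1).
    rho : latent correlation between any two classifiers, in [0, 1).
    seed : master seed; label and score streams derive independent
        substreams from it so adding classifiers never perturbs labels.
    """

    n: int = 2000
    prevalence: float = 0.73
    aucs: tuple[float, ...] = (0.85, 0.88, 0.90)
    rho: float = 0.3
    seed: int = 0
    catalog: ClassCatalog = field(default_factory=lambda: DEFAULT_CATALOG)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("n must be >= 2")
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError("prevalence must lie in (0, 1)")
        if not self.aucs:
            raise ValidationError("need at least one target AUC")
        if any(not (0.5 < a < 1.0) for a in self.aucs):
            raise ValidationError("every target AUC must lie in (0.5, 1)")
        if not (0.0 <= self.rho < 1.0):
            raise ValidationError("rho must lie in [0, 1)")
        if len(self.catalog.classes) != 2:
            raise ValidationError("simulator supports binary catalogs only")


def _substreams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    ss_labels, ss_scores = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(ss_labels), np.random.default_rng(ss_scores)


def simulate_labels(config: SimulatorConfig) -> LabelVector:
    """Draw i.i.d. labels, positive with the configured prevalence."""
    rng, _ = _substreams(config.seed)
    pos = rng.random(config.n) < config.prevalence
    neg_name = next(
        c for c in config.catalog.classes if c != config.catalog.positive
    )
    labels = tuple(
        config.catalog.positive if p else neg_name for p in pos
    )
    ids = tuple(f"s{i:06d}" for i in range(config.n))
    return LabelVector(ids, labels, config.catalog)


def simulate_scores(
    labels: LabelVector, config: SimulatorConfig
) -> ClassifierBundle:
    """Generate the correlated probability tables of all K classifiers.

    Single-class label vectors are permitted (the bundle is still a
    valid score container) but make AUC computation on the result
    undefined downstream.
    """
    _, rng = _substreams(config.seed)
    n = len(labels)
    k = len(config.aucs)
    pos = np.asarray(labels.labels) == labels.catalog.positive
    shared = rng.standard_normal(n)
    noise = rng.standard_normal((k, n))
    latent = np.sqrt(config.rho) * shared + np.sqrt(1.0 - config.rho) * noise
    shifts = np.sqrt(2.0) * ndtri(np.asarray(config.aucs))
    latent = latent + shifts[:, None] * pos[None, :]
    p_pos = expit(latent)  # strictly increasing: preserves each AUC

    pos_idx = labels.catalog.positive_index
    tables = []
    for i in range(k):
        probs = np.empty((n, len(labels.catalog.classes)))
        # binary catalog: remaining mass goes to the other class
        for ci in range(len(labels.catalog.classes)):
            probs[:, ci] = p_pos[i] if ci == pos_idx else 1.0 - p_pos[i]
        tables.append(
            ProbabilityTable(
                name=f"learner_{i + 1}",
                sample_ids=labels.sample_ids,
                probabilities=probs,
                catalog=labels.catalog,
            )
        )
    return ClassifierBundle(tables)


def simulate_bundle(
    config: SimulatorConfig,
) -> tuple[LabelVector, ClassifierBundle]:
    """Labels plus scores in one call (the common entry point)."""
    labels = simulate_labels(config)
    return labels, simulate_scores(labels, config)


def binormal_auc(d: float) -> float:
    """Closed-form AUC Φ(d/√2) of the equal-variance binormal model."""
    from scipy.special import ndtr

    return float(ndtr(d / np.sqrt(2.0)))


__all__ = [
    "DEFAULT_CATALOG",
    "SimulatorConfig",
    "simulate_labels",
    "simulate_scores",
    "simulate_bundle",
    "binormal_auc",
]
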