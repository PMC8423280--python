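"""Paired and group-wise model comparison tests.

Two tests support the claim that a fused model differs from its base
learners:

* **McNemar's test** on paired per-sample correctness.  Only the
  discordant counts matter: b = samples model A got wrong and B right,
  c = the reverse.  Small discordant totals (b + c < 25) use the exact
  two-sided binomial test under X ~ Binomial(b+c, 1/2); larger totals
  use the continuity-corrected chi-square (|b−c|−1)²/(b+c) on 1 df.
* **One-way ANOVA** on per-fold metric values (e.g. the five fold
  accuracies of two models form two groups of five replicates), the
  classical F ratio of between-group to within-group mean square.

Decisions are reported at the conventional α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import LabelVector
from .errors import AlignmentError, ValidationError

ALPHA = 0.05

#: Discordant-count threshold below which the exact binomial variant is used.
EXACT_SWITCH = 25


@dataclass(frozen=True)
class PairedOutcomes:
    """Correctness contingency of two models over shared samples.

    ``n_ab`` counts samples where A's correctness is a and B's is b
    (1 = correct).  Orientation of the discordant counts is fixed:
    ``b`` = A wrong & B right (n01), ``c`` = A right & B wrong (n10).
    """

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        if min(self.n00, self.n01, self.n10, self.n11) < 0:
            raise ValidationError("outcome counts must be non-negative")

    @property
    def b(self) -> int:
        return self.n01

    @property
    def c(self) -> int:
        return self.n10

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test at α = 0.05."""

    test: str
    statistic: float | None
    p_value: float
    variant: str
    reject: bool
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def paired_outcomes(
    labels: LabelVector,
    preds_a: Sequence[str],
    preds_b: Sequence[str],
) -> PairedOutcomes:
    """Cross-tabulate per-sample correctness of two prediction lists."""
    n = len(labels)
    if len(preds_a) != n or len(preds_b) != n:
        raise AlignmentError(
            f"predictions ({len(preds_a)}, {len(preds_b)}) do not match "
            f"{n} labels"
        )
    y = np.asarray(labels.labels)
    a = np.asarray(preds_a) == y
    b = np.asarray(preds_b) == y
    return PairedOutcomes(
        n00=int(np.sum(~a & ~b)),
        n01=int(np.sum(~a & b)),
        n10=int(np.sum(a & ~b)),
        n11=int(np.sum(a & b)),
    )


def mcnemar_test(outcomes: PairedOutcomes) -> TestResult:
    """McNemar's test on the discordant pair counts.

    Exact two-sided binomial p = min(1, 2·P(X ≤ min(b,c))) for
    b + c < 25, else continuity-corrected chi-square on 1 df.  Zero
    discordance returns p = 1 with a degenerate flag (the two models
    never disagree, so no asymmetry can be tested).
    """
    b, c = outcomes.b, outcomes.c
    m = b + c
    if m == 0:
        return TestResult(
            test="mcnemar",
            statistic=None,
            p_value=1.0,
            variant="degenerate",
            reject=False,
            note="no discordant pairs",
        )
    if m < EXACT_SWITCH:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), m, 0.5)))
        return TestResult("mcnemar", None, p, "exact", p < ALPHA)
    chi2 = (abs(b - c) - 1.0) ** 2 / m
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult("mcnemar", chi2, p, "asymptotic", p < ALPHA)


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way ANOVA F test across groups of metric values.

    Groups are typically per-fold values of one metric for each model
    being compared (g groups, N values total; F on (g−1, N−g) df).
    All-identical data yields F = 0, p = 1 with a degenerate flag.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every ANOVA group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(
            test="anova",
            statistic=0.0,
            p_value=1.0,
            variant="degenerate",
            reject=False,
            note="zero variance: all values identical",
        )
    within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if within == 0.0:
        # perfect group separation: F diverges
        return TestResult("anova", float("inf"), 0.0, "classical", True,
                          note="zero within-group variance")
    f_stat, p = stats.f_oneway(*arrays)
    return TestResult("anova", float(f_stat), float(p), "classical", p < ALPHA)


__all__ = [
    "ALPHA",
    "EXACT_SWITCH",
    "PairedOutcomes",
    "TestResult",
    "paired_outcomes",
    "mcnemar_test",
    "one_way_anova",
]
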