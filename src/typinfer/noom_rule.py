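"""Error rates of the N-out-of-M majority decision rule.

The rule tests M subjects, each yielding one qualitative outcome drawn from
a population distribution whose modal outcome is the "representative" and
whose remaining outcomes are "outliers" with total probability omega.  An
outcome is declared representative when it appears in a strict majority
(at least floor(M/2) + 1) of the M subjects.  A sample is then

* correct       — the representative outcome reached the majority,
* incorrect     — some outlier outcome reached the majority,
* inconclusive  — no outcome reached the majority.

Because at most one outcome can hold a strict majority, the three events
are disjoint and their probabilities follow from binomial tails: each
outcome's count is marginally Binomial(M, its probability), so the chance
it reaches the threshold t is P(X >= t), and the incorrect rate delta sums
this over the outlier outcomes.  For M = 1 the rule reduces to trusting a
single subject and delta equals omega.

A brute-force check, :func:`enumerate_exact`, sums multinomial
probabilities over all K^M ordered outcome assignments and must agree with
the analytic rates to floating-point precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .exceptions import InputDomainError, ResourceGuardError

__all__ = [
    "OutcomeDistribution",
    "DecisionRates",
    "Decision",
    "majority_threshold",
    "classify_sample",
    "rule_rates",
    "delta_curve",
    "delta_difference",
    "omega_threshold",
    "min_typicality_percent",
    "enumerate_exact",
]

_SUM_TOL = 1e-12
_ENUM_GUARD = 10**7


class Decision(str, Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class OutcomeDistribution:
    """Qualitative outcome probabilities; the first label is the representative.

    The representative must be the strict modal outcome; the total outlier
    probability is ``omega = 1 - probs[0]``.
    """

    probs: tuple
    labels: tuple = ()

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "probs", probs)
        if len(probs) < 1:
            raise InputDomainError("at least one outcome is required")
        labels = tuple(self.labels) if self.labels else tuple(
            ["representative"] + [f"outlier_{j}" for j in range(1, len(probs))]
        )
        if len(labels) != len(probs):
            raise InputDomainError("labels and probs must align")
        object.__setattr__(self, "labels", labels)
        if any(p < 0.0 for p in probs):
            raise InputDomainError("outcome probabilities must be non-negative")
        total = math.fsum(probs)
        if abs(total - 1.0) > _SUM_TOL:
            raise InputDomainError(
                f"outcome probabilities must sum to 1 (got {total!r})"
            )
        if len(probs) > 1 and probs[0] <= max(probs[1:]):
            raise InputDomainError(
                "the representative (first) outcome must be the strict maximum"
            )

    @classmethod
    def single_outlier(cls, omega: float) -> "OutcomeDistribution":
        """Distribution (1 - omega, omega) with one outlier type."""
        if not 0.0 <= omega < 0.5:
            raise InputDomainError(
                f"single-outlier omega must lie in [0, 0.5), got {omega}"
            )
        if omega == 0.0:
            return cls(probs=(1.0,))
        return cls(probs=(1.0 - omega, omega))

    @property
    def omega(self) -> float:
        """Total outlier probability."""
        return 1.0 - self.probs[0]

    @property
    def n_outcomes(self) -> int:
        return len(self.probs)


@dataclass(frozen=True)
class DecisionRates:
    """Correct (pi), incorrect (delta) and inconclusive probabilities."""

    correct: float
    incorrect: float
    inconclusive: float

    def __post_init__(self) -> None:
        for name in ("correct", "incorrect", "inconclusive"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise InputDomainError(f"{name} rate out of [0, 1]: {v}")
        total = self.correct + self.incorrect + self.inconclusive
        if abs(total - 1.0) > 1e-9:
            raise InputDomainError(f"rates must sum to 1, got {total!r}")

    @property
    def pi(self) -> float:
        return self.correct

    @property
    def delta(self) -> float:
        return self.incorrect


def majority_threshold(m: int) -> int:
    """Smallest count forming a strict majority of ``m`` subjects."""
    if not isinstance(m, int) or isinstance(m, bool) or m < 1:
        raise InputDomainError(f"M must be an integer >= 1, got {m!r}")
    return m // 2 + 1


def classify_sample(counts, m: int | None = None) -> Decision:
    """Classify one sample of outcome counts under the majority rule.

    ``counts`` aligns with the outcome labels (first entry = representative).
    """
    counts = list(counts)
    total = sum(counts)
    if m is None:
        m = total
    if total != m:
        raise InputDomainError(f"counts sum to {total}, expected M={m}")
    t = majority_threshold(m)
    if counts[0] >= t:
        return Decision.CORRECT
    if any(c >= t for c in counts[1:]):
        return Decision.INCORRECT
    return Decision.INCONCLUSIVE


def rule_rates(dist: OutcomeDistribution, m: int) -> DecisionRates:
    """Analytic decision rates of the majority rule for ``m`` subjects.

    Majority events are disjoint, so correct = P(X_rep >= t) and incorrect
    sums the same tail over the outlier outcomes, each count marginally
    binomial; the remainder is inconclusive.
    """
    t = majority_threshold(m)
    correct = float(stats.binom.sf(t - 1, m, dist.probs[0]))
    incorrect = float(
        math.fsum(stats.binom.sf(t - 1, m, p) for p in dist.probs[1:])
    )
    inconclusive = 1.0 - correct - incorrect
    return DecisionRates(
        correct=correct,
        incorrect=incorrect,
        inconclusive=max(inconclusive, 0.0) if inconclusive > -1e-12 else inconclusive,
    )


def _delta_single(m: int, omega: np.ndarray) -> np.ndarray:
    t = majority_threshold(m)
    return stats.binom.sf(t - 1, m, omega)


def delta_curve(m: int, omega_grid) -> np.ndarray:
    """Incorrect-conclusion rate delta(omega) with a single outlier type.

    For the 2-out-of-3 rule this is the closed form 3*w^2 - 2*w^3; it is
    strictly increasing on the admissible range [0, 0.5), beyond which the
    representative would no longer be the modal outcome.
    """
    omega = np.atleast_1d(np.asarray(omega_grid, dtype=float))
    if np.any((omega < 0.0) | (omega >= 0.5)):
        raise InputDomainError("each omega must lie in [0, 0.5)")
    return np.asarray(_delta_single(m, omega), dtype=float)


def delta_difference(omega) -> np.ndarray | float:
    """Reduction in delta when moving from 1-out-of-1 to 2-out-of-3.

    Equals omega - (3*omega^2 - 2*omega^3); non-negative on [0, 0.5) and
    maximal near omega = 0.211, so the benefit of the majority rule is
    concentrated at intermediate outlier probabilities.
    """
    scalar = np.isscalar(omega)
    diff = delta_curve(1, omega) - delta_curve(3, omega)
    return float(diff[0]) if scalar else diff


def omega_threshold(m: int, delta_target: float) -> float:
    """Outlier probability at which the single-outlier delta hits a target.

    Solves delta(omega) = delta_target for the unique root in (0, 0.5);
    the companion typicality threshold is 1 - omega.
    """
    upper = float(_delta_single(m, np.array([0.5 - 1e-13]))[0])
    if not 0.0 < delta_target < upper:
        raise InputDomainError(
            f"delta_target must lie in (0, {upper:.6g}) for M={m}"
        )
    f = lambda w: float(_delta_single(m, np.array([w]))[0]) - delta_target
    return float(brentq(f, 1e-15, 0.5 - 1e-13, xtol=1e-12))


def min_typicality_percent(m: int, delta_target: float = 0.05) -> int:
    """Smallest integer-percent typicality keeping delta at or below target.

    Scans integer-percent outlier probabilities, finds the largest one whose
    single-outlier delta does not exceed ``delta_target``, and returns the
    complementary typicality 100 - omega_percent.
    """
    admissible = [
        w for w in range(0, 50)
        if float(_delta_single(m, np.array([w / 100.0]))[0]) <= delta_target
    ]
    if not admissible:
        raise InputDomainError("no integer-percent omega meets the target")
    return 100 - max(admissible)


def enumerate_exact(dist: OutcomeDistribution, m: int) -> DecisionRates:
    """Brute-force decision rates by exhausting all K^M ordered assignments.

    Serves as an independent oracle for :func:`rule_rates`; guarded against
    instances with more than 10^7 assignments.
    """
    k = dist.n_outcomes
    if k**m > _ENUM_GUARD:
        raise ResourceGuardError(
            f"enumeration of {k}^{m} assignments exceeds the guard of {_ENUM_GUARD}"
        )
    t = majority_threshold(m)
    totals = {Decision.CORRECT: [], Decision.INCORRECT: [], Decision.INCONCLUSIVE: []}
    probs = dist.probs
    for assignment in itertools.product(range(k), repeat=m):
        prob = 1.0
        counts = [0] * k
        for outcome in assignment:
            prob *= probs[outcome]
            counts[outcome] += 1
        if counts[0] >= t:
            decision = Decision.CORRECT
        elif any(c >= t for c in counts[1:]):
            decision = Decision.INCORRECT
        else:
            decision = Decision.INCONCLUSIVE
        totals[decision].append(prob)
    return DecisionRates(
        correct=math.fsum(totals[Decision.CORRECT]),
        incorrect=math.fsum(totals[Decision.INCORRECT]),
        inconclusive=math.fsum(totals[Decision.INCONCLUSIVE]),
    )
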