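"""Exact confidence bounds for a binomial success probability.

Given a tally of N subjects showing an outcome out of M tested, the
equal-tailed exact (Clopper-Pearson) interval for the per-subject success
probability p is obtained by inverting the binomial tail probabilities:

* the lower bound ``p_L`` is the largest p0 with ``P(X >= N | M, p0)`` equal
  to the allotted tail mass,
* the upper bound ``p_U`` is the smallest p0 with ``P(X <= N | M, p0)`` equal
  to that tail mass,

where the tail mass is ``(1 - level) / 2`` for a two-sided interval and
``1 - level`` for a one-sided (lower-only) interval.  Both defining
equations have closed-form solutions through the incomplete-beta identity
``P(X >= N | M, p) = I_p(N, M - N + 1)``, so the bounds are beta quantiles.
The conventional edge cases are ``p_L = 0`` at N = 0 and ``p_U = 1`` at
N = M.

These exact bounds are deliberately conservative (coverage at least the
nominal level for every p); no approximate or mid-p variant is offered
because downstream typicality tables depend on the exact construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from scipy import stats

from .exceptions import InputDomainError, UnsupportedRequestError

__all__ = [
    "Sidedness",
    "SampleTally",
    "ProportionInterval",
    "binomial_pmf",
    "lower_bound_p",
    "upper_bound_p",
    "proportion_interval",
]


class Sidedness(str, Enum):
    """Sidedness of a confidence statement (lower-only or equal-tailed)."""

    ONE_SIDED_LOWER = "one_sided_lower"
    TWO_SIDED = "two_sided"

    @classmethod
    def parse(cls, value: "str | Sidedness") -> "Sidedness":
        if isinstance(value, Sidedness):
            return value
        key = str(value).strip().lower()
        aliases = {
            "one": cls.ONE_SIDED_LOWER,
            "one_sided": cls.ONE_SIDED_LOWER,
            "one_sided_lower": cls.ONE_SIDED_LOWER,
            "two": cls.TWO_SIDED,
            "two_sided": cls.TWO_SIDED,
        }
        if key not in aliases:
            raise InputDomainError(f"unknown sidedness: {value!r}")
        return aliases[key]

    def tail_mass(self, level: float) -> float:
        """Tail probability allotted to the lower bound at this sidedness."""
        return (1.0 - level) / 2.0 if self is Sidedness.TWO_SIDED else 1.0 - level


def _check_level(level: float) -> None:
    if not 0.0 < level < 1.0:
        raise InputDomainError(f"confidence level must be in (0, 1), got {level}")


@dataclass(frozen=True)
class SampleTally:
    """N subjects showing the outcome out of M tested."""

    n_positive: int
    m_tested: int

    def __post_init__(self) -> None:
        for name in ("n_positive", "m_tested"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise InputDomainError(f"{name} must be an integer, got {v!r}")
        if self.m_tested < 1:
            raise InputDomainError("m_tested must be >= 1")
        if not 0 <= self.n_positive <= self.m_tested:
            raise InputDomainError(
                f"need 0 <= N <= M, got N={self.n_positive}, M={self.m_tested}"
            )


@dataclass(frozen=True)
class ProportionInterval:
    """Exact confidence bounds for the binomial success probability p."""

    lower: float
    upper: float
    level: float
    sidedness: Sidedness = field(default=Sidedness.TWO_SIDED)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise InputDomainError(
                f"bounds must satisfy 0 <= lower <= upper <= 1, "
                f"got [{self.lower}, {self.upper}]"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


def binomial_pmf(i: int, m: int, p: float) -> float:
    """Probability of exactly ``i`` successes in ``m`` trials at rate ``p``."""
    if not isinstance(i, int) or not isinstance(m, int) or isinstance(i, bool):
        raise InputDomainError("counts i and m must be integers")
    if m < 0 or not 0 <= i <= m:
        raise InputDomainError(f"need 0 <= i <= m, got i={i}, m={m}")
    if not 0.0 <= p <= 1.0:
        raise InputDomainError(f"probability p must be in [0, 1], got {p}")
    return float(stats.binom.pmf(i, m, p))


def lower_bound_p(
    tally: SampleTally,
    level: float = 0.95,
    sidedness: "str | Sidedness" = Sidedness.TWO_SIDED,
) -> float:
    """Exact lower confidence bound for p given the tally.

    Solves ``P(X >= N | M, p_L) = tail`` via the beta-quantile identity;
    returns 0 when N = 0.
    """
    _check_level(level)
    sidedness = Sidedness.parse(sidedness)
    n, m = tally.n_positive, tally.m_tested
    if n == 0:
        return 0.0
    tail = sidedness.tail_mass(level)
    return float(stats.beta.ppf(tail, n, m - n + 1))


def upper_bound_p(
    tally: SampleTally,
    level: float = 0.95,
    sidedness: "str | Sidedness" = Sidedness.TWO_SIDED,
) -> float:
    """Exact upper confidence bound for p (two-sided intervals only).

    Solves ``P(X <= N | M, p_U) = tail``; returns 1 when N = M.  One-sided
    intervals in this package are lower-only, so requesting an upper bound
    under ``one_sided_lower`` raises :class:`UnsupportedRequestError`.
    """
    _check_level(level)
    sidedness = Sidedness.parse(sidedness)
    if sidedness is not Sidedness.TWO_SIDED:
        raise UnsupportedRequestError(
            "upper bound is only defined for two-sided intervals"
        )
    n, m = tally.n_positive, tally.m_tested
    if n == m:
        return 1.0
    tail = sidedness.tail_mass(level)
    return float(stats.beta.ppf(1.0 - tail, n + 1, m - n))


def proportion_interval(
    tally: SampleTally,
    level: float = 0.95,
    sidedness: "str | Sidedness" = Sidedness.TWO_SIDED,
) -> ProportionInterval:
    """Bundle the exact bounds; one-sided intervals take upper = 1."""
    sidedness = Sidedness.parse(sidedness)
    lower = lower_bound_p(tally, level, sidedness)
    if sidedness is Sidedness.TWO_SIDED:
        upper = upper_bound_p(tally, level, sidedness)
    else:
        upper = 1.0
    return ProportionInterval(lower=lower, upper=upper, level=level, sidedness=sidedness)
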