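"""Monte Carlo verification of the analytic results.

Every closed-form quantity in the package — majority-rule decision rates,
the mixture linking typicality to per-subject significance, and the
coverage of the typicality lower bound — can be checked by simulation.
Each run uses a single seeded ``numpy.random.Generator``; identical
configurations therefore yield bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binomial_ci import SampleTally, Sidedness
from .exceptions import InputDomainError
from .noom_rule import DecisionRates, OutcomeDistribution, majority_threshold
from .typicality import TestCharacteristics, gamma_lower_bound

__all__ = [
    "SimulationConfig",
    "simulate_rule",
    "simulate_significance",
    "coverage_check",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Replication count, seed and scenario for a simulation run."""

    n_reps: int
    seed: int
    m_tested: int
    dist: OutcomeDistribution | None = None
    gamma: float | None = None
    characteristics: TestCharacteristics = field(default_factory=TestCharacteristics)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise InputDomainError("n_reps must be >= 1")
        if self.m_tested < 1:
            raise InputDomainError("m_tested must be >= 1")
        if self.dist is None and self.gamma is None:
            raise InputDomainError("provide either an outcome distribution or gamma")


def simulate_rule(
    dist: OutcomeDistribution,
    m: int,
    n_reps: int,
    seed: int,
) -> DecisionRates:
    """Empirical majority-rule decision rates.

    Each replicate draws one outcome per subject from the distribution and
    applies the strict-majority classification; the returned empirical rates
    converge on :func:`typinfer.noom_rule.rule_rates` at the usual
    root-n rate.
    """
    rng = np.random.default_rng(seed)
    t = majority_threshold(m)
    probs = np.asarray(dist.probs)
    # one row per replicate, one column per subject (subjects vary fastest)
    outcomes = rng.choice(len(probs), size=(n_reps, m), p=probs)
    counts = np.stack(
        [(outcomes == j).sum(axis=1) for j in range(len(probs))], axis=1
    )
    correct = counts[:, 0] >= t
    incorrect = (counts[:, 1:] >= t).any(axis=1) if counts.shape[1] > 1 else np.zeros(
        n_reps, dtype=bool
    )
    n_correct = int(correct.sum())
    n_incorrect = int(incorrect.sum())
    return DecisionRates(
        correct=n_correct / n_reps,
        incorrect=n_incorrect / n_reps,
        inconclusive=(n_reps - n_correct - n_incorrect) / n_reps,
    )


def _draw_significant(
    gamma: float,
    tc: TestCharacteristics,
    m: int,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-stage draw: carrier status, then an imperfect per-subject test."""
    if not 0.0 <= gamma <= 1.0:
        raise InputDomainError(f"gamma must be in [0, 1], got {gamma}")
    carrier = rng.random((n_reps, m)) < gamma
    p_sig = np.where(carrier, tc.beta, tc.alpha)
    return (rng.random((n_reps, m)) < p_sig).sum(axis=1)


def simulate_significance(
    gamma: float,
    tc: TestCharacteristics,
    m: int,
    n_reps: int,
    seed: int,
) -> np.ndarray:
    """Empirical distribution of N, the count of significant subjects.

    Each subject carries the effect with probability gamma and tests
    significant with probability beta if a carrier, alpha otherwise, so the
    mean of N/M converges to p = alpha + (beta - alpha) * gamma.  Returns
    counts of N over replicates as an array of length M + 1.
    """
    rng = np.random.default_rng(seed)
    n_sig = _draw_significant(gamma, tc, m, n_reps, rng)
    return np.bincount(n_sig, minlength=m + 1)


def coverage_check(
    gamma: float,
    tc: TestCharacteristics,
    m: int,
    level: float = 0.95,
    sidedness: "str | Sidedness" = Sidedness.TWO_SIDED,
    n_reps: int = 100_000,
    seed: int = 0,
) -> float:
    """Empirical coverage of the typicality lower bound gamma_c.

    Fraction of replicates whose bound does not exceed the true gamma;
    exact binomial bounds are conservative, so this should sit at or above
    the nominal level.
    """
    sidedness = Sidedness.parse(sidedness)
    rng = np.random.default_rng(seed)
    n_sig = _draw_significant(gamma, tc, m, n_reps, rng)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        bounds = np.array(
            [
                gamma_lower_bound(SampleTally(n, m), tc, level, sidedness).gamma_c
                for n in range(m + 1)
            ]
        )
    return float(np.mean(bounds[n_sig] <= gamma))
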