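"""Typicality (prevalence) bounds from per-subject test results.

The probability that a subject's test comes out significant is not the
population typicality gamma itself, because per-subject tests err: with
false-positive rate alpha and sensitivity (true-positive rate) beta, the
per-subject significance probability is the mixture

    p = gamma * beta + (1 - gamma) * alpha = alpha + (beta - alpha) * gamma,

an affine, strictly increasing map of gamma onto [alpha, beta].  Inverting
it, gamma = (p - alpha) / (beta - alpha).  Substituting the exact lower
confidence bound for p (from :mod:`typinfer.binomial_ci`) yields a lower
confidence bound gamma_c on typicality — the largest population fraction
the observed tally can conservatively vouch for.

Two caveats are inherent to the map.  The raw inverse can be negative when
the bound on p falls below alpha (few positives in a small sample), and it
exceeds one when beta < 1 pushes the denominator down; both are reported
clipped to [0, 1] with the raw value kept alongside.  Sensitivity below one
inflates gamma_c without limit, so the conservative default is beta = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up
from .binomial_ci import SampleTally, Sidedness, lower_bound_p
from .exceptions import InputDomainError

__all__ = [
    "TestCharacteristics",
    "TypicalityBound",
    "p_from_gamma",
    "gamma_from_p",
    "gamma_lower_bound",
    "gamma_table",
    "gamma_sensitivity",
]


@dataclass(frozen=True)
class TestCharacteristics:
    """Per-subject test error rates: false-positive rate and sensitivity.

    The default ``alpha=0.05, beta=1`` is the conservative standard: any
    beta < 1 makes the implied typicality bound arbitrarily large, so
    sensitivity is assumed perfect unless the user explicitly overrides it.
    """

    alpha: float = 0.05
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < self.beta <= 1.0:
            raise InputDomainError(
                f"need 0 <= alpha < beta <= 1, got alpha={self.alpha}, beta={self.beta}"
            )


@dataclass(frozen=True)
class TypicalityBound:
    """Lower confidence bound on typicality, with the unclipped diagnostic."""

    gamma_c: float
    raw: float
    clipped: bool
    level: float
    sidedness: Sidedness
    characteristics: TestCharacteristics
    tally: SampleTally | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_c <= 1.0:
            raise InputDomainError("clipped gamma_c must lie in [0, 1]")

    @property
    def percent(self) -> float:
        return 100.0 * self.gamma_c


def p_from_gamma(gamma: float, tc: TestCharacteristics) -> float:
    """Per-subject significance probability implied by typicality ``gamma``."""
    if not 0.0 <= gamma <= 1.0:
        raise InputDomainError(f"gamma must be in [0, 1], got {gamma}")
    return tc.alpha + (tc.beta - tc.alpha) * gamma


def gamma_from_p(p: float, tc: TestCharacteristics, clip: bool = True) -> float:
    """Typicality implied by a per-subject significance probability ``p``.

    Inverse of :func:`p_from_gamma` on [alpha, beta].  Outside that range
    the raw value is negative or exceeds one; ``clip`` truncates to [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise InputDomainError(f"p must be in [0, 1], got {p}")
    raw = (p - tc.alpha) / (tc.beta - tc.alpha)
    if clip:
        return min(max(raw, 0.0), 1.0)
    return raw


def gamma_lower_bound(
    tally: SampleTally,
    tc: TestCharacteristics = TestCharacteristics(),
    level: float = 0.95,
    sidedness: "str | Sidedness" = Sidedness.TWO_SIDED,
) -> TypicalityBound:
    """Lower confidence bound gamma_c on typicality for a tally.

    Composes the exact lower bound on the significance probability with the
    error-rate correction; the result is non-decreasing in N at fixed M.
    """
    sidedness = Sidedness.parse(sidedness)
    if tc.beta < 1.0:
        warnings.warn(
            "sensitivity beta < 1 inflates the typicality bound without limit; "
            "the conservative convention is beta = 1",
            UserWarning,
            stacklevel=2,
        )
    p_l = lower_bound_p(tally, level, sidedness)
    raw = gamma_from_p(p_l, tc, clip=False)
    clipped_value = min(max(raw, 0.0), 1.0)
    return TypicalityBound(
        gamma_c=clipped_value,
        raw=raw,
        clipped=clipped_value != raw,
        level=level,
        sidedness=sidedness,
        characteristics=tc,
        tally=tally,
    )


def gamma_table(
    m_max: int,
    tc: TestCharacteristics = TestCharacteristics(),
    level: float = 0.95,
    sidedness: "str | Sidedness" = Sidedness.TWO_SIDED,
    percent: bool = True,
    rounded: bool = False,
) -> pd.DataFrame:
    """Lower-triangular table of gamma_c for M = 1..m_max, N = 0..M.

    Rows are indexed by M, columns by N; cells with N > M are NaN.  With
    ``percent`` the values are on the percent scale; ``rounded`` applies the
    table-emission convention of one decimal place, ties away from zero.
    """
    if m_max < 1:
        raise InputDomainError("m_max must be >= 1")
    sidedness = Sidedness.parse(sidedness)
    data = np.full((m_max, m_max + 1), np.nan)
    for m in range(1, m_max + 1):
        for n in range(0, m + 1):
            bound = gamma_lower_bound(SampleTally(n, m), tc, level, sidedness)
            value = bound.percent if percent else bound.gamma_c
            if rounded:
                value = round_half_up(value, 1 if percent else 3)
            data[m - 1, n] = value
    return pd.DataFrame(
        data,
        index=pd.Index(range(1, m_max + 1), name="M"),
        columns=pd.Index(range(0, m_max + 1), name="N"),
    )


def gamma_sensitivity(
    tally: SampleTally,
    alpha_grid,
    beta_grid,
    level: float = 0.95,
    sidedness: "str | Sidedness" = Sidedness.ONE_SIDED_LOWER,
) -> pd.DataFrame:
    """gamma_c along a grid of test characteristics.

    ``alpha_grid`` and ``beta_grid`` are broadcast against each other
    (a scalar or length-1 grid pairs with every entry of the other), so a
    sweep over alpha at fixed beta, or over beta at fixed alpha, is a single
    call.  Every pair must satisfy alpha < beta.  gamma_c falls as alpha
    grows and rises as beta shrinks.
    """
    alphas, betas = np.broadcast_arrays(
        np.atleast_1d(np.asarray(alpha_grid, dtype=float)),
        np.atleast_1d(np.asarray(beta_grid, dtype=float)),
    )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for a, b in zip(alphas.ravel(), betas.ravel()):
            tc = TestCharacteristics(alpha=float(a), beta=float(b))
            bound = gamma_lower_bound(tally, tc, level, sidedness)
            rows.append(
                {
                    "alpha": float(a),
                    "beta": float(b),
                    "gamma_c": bound.gamma_c,
                    "gamma_c_raw": bound.raw,
                }
            )
    return pd.DataFrame(rows)
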