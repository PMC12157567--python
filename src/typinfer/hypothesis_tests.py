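"""One-sided binomial tests of null hypotheses about typicality.

A hypothesized typicality gamma0 implies a per-subject significance
probability p0 = alpha + (beta - alpha) * gamma0.  The one-sided p-value
for observing N significant subjects out of M is the upper-tail binomial
probability P(X >= N | M, p0): the chance, under the null, of a tally at
least as favourable to high typicality as the one observed.

Two nulls are of standing interest:

* majority null, gamma0 = 0.5 — typicality below one half, i.e. the effect
  is not present in a majority of the population.  Under the default test
  characteristics p0 = 0.525, so even a unanimous small sample carries
  limited evidence (p = 0.525^M along the N = M diagonal).
* global null, gamma0 = 0 — the effect is absent from every member of the
  population, p0 = alpha.  A single significant subject already rejects at
  level alpha (p = 0.05 for 1-out-of-1).

Note on tail direction: the defining event is "N or more" significant
subjects.  Some narrative descriptions phrase it as "N or less", but the
tabulated values (e.g. 0.525 for 1-out-of-1 under the majority null, not 1)
identify the upper tail unambiguously; this package implements the upper
tail and flags the wording discrepancy here rather than silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .binomial_ci import SampleTally
from .exceptions import InputDomainError
from .typicality import TestCharacteristics, p_from_gamma

__all__ = [
    "TypicalityNull",
    "majority_null",
    "global_null",
    "typicality_pvalue",
    "pvalue_table",
    "round_pvalue",
    "format_pvalue",
]


@dataclass(frozen=True)
class TypicalityNull:
    """A hypothesized typicality value together with the test error rates."""

    gamma0: float
    characteristics: TestCharacteristics = field(default_factory=TestCharacteristics)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma0 <= 1.0:
            raise InputDomainError(f"gamma0 must be in [0, 1], got {self.gamma0}")

    @property
    def p0(self) -> float:
        """Per-subject significance probability implied by the null."""
        return p_from_gamma(self.gamma0, self.characteristics)


def majority_null(tc: TestCharacteristics = TestCharacteristics()) -> TypicalityNull:
    return TypicalityNull(gamma0=0.5, characteristics=tc)


def global_null(tc: TestCharacteristics = TestCharacteristics()) -> TypicalityNull:
    return TypicalityNull(gamma0=0.0, characteristics=tc)


def typicality_pvalue(tally: SampleTally, null: TypicalityNull) -> float:
    """Upper-tail p-value P(X >= N | M, p0) for the hypothesized typicality."""
    n, m = tally.n_positive, tally.m_tested
    return float(stats.binom.sf(n - 1, m, null.p0))


def pvalue_table(
    m_max: int,
    null: TypicalityNull,
    rounded: bool = False,
) -> pd.DataFrame:
    """Table of p-values for M = 1..m_max, N = 0..M (NaN above the diagonal).

    With ``rounded`` the emission convention applies: four decimal places,
    except values below 1e-4 which keep three significant digits.
    """
    if m_max < 1:
        raise InputDomainError("m_max must be >= 1")
    data = np.full((m_max, m_max + 1), np.nan)
    for m in range(1, m_max + 1):
        for n in range(0, m + 1):
            p = typicality_pvalue(SampleTally(n, m), null)
            data[m - 1, n] = round_pvalue(p) if rounded else p
    return pd.DataFrame(
        data,
        index=pd.Index(range(1, m_max + 1), name="M"),
        columns=pd.Index(range(0, m_max + 1), name="N"),
    )


def round_pvalue(p: float) -> float:
    """Numeric rounding used for table emission (see :func:`format_pvalue`)."""
    if 0.0 < p < 1e-4:
        return float(f"{p:.2e}")
    return round_half_up(p, 4)


def format_pvalue(p: float) -> str:
    """Display form: 4 decimals, trailing zeros trimmed; tiny values in
    scientific notation with 3 significant digits and a bare exponent
    (e.g. ``3.13e-7``)."""
    if 0.0 < p < 1e-4:
        mantissa, exponent = f"{p:.2e}".split("e")
        return f"{mantissa}e{int(exponent)}"
    text = f"{round_half_up(p, 4):.4f}".rstrip("0").rstrip(".")
    return text if text else "0"
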