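"""Report builders: reference tables and figure data series as CSV/JSON.

Each report reproduces one of the package's standard artifacts with its
default parameters (alpha = 0.05, beta = 1, level = 0.95, M up to 10):

* ``table1`` / ``table2`` — typicality lower bounds gamma_c (percent) from
  two-sided / one-sided 95% intervals,
* ``table3`` / ``table4`` — p-values for the majority null (gamma0 = 0.5)
  and the global null (gamma0 = 0),
* ``fig1``   — single-outlier delta curves for 1-oo-1 and 2-oo-3 and their
  difference over an omega grid,
* ``fig2``   — two-sided 95% confidence belts for p and gamma over all
  tallies at M in {1, 2, 3, 4, 5, 10},
* ``fig3c``  — gamma_c against the false-positive rate alpha (beta = 1),
* ``fig3d``  — gamma_c against the sensitivity beta (alpha = 0.01, per the
  convention for that sweep).

Figure reports are emitted as numeric data series (grid point, value), not
rendered images; rendering, if wanted, is left to the caller's plotting
stack.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .binomial_ci import SampleTally, Sidedness, proportion_interval
from .exceptions import InputDomainError
from .hypothesis_tests import TypicalityNull, pvalue_table
from .noom_rule import delta_curve, delta_difference
from .typicality import (
    TestCharacteristics,
    gamma_from_p,
    gamma_sensitivity,
    gamma_table,
)

__all__ = ["ReportRequest", "run_report", "REPORT_KINDS"]

logger = logging.getLogger(__name__)

REPORT_KINDS = (
    "table1",
    "table2",
    "table3",
    "table4",
    "fig1",
    "fig2",
    "fig3c",
    "fig3d",
)

_FIG2_M_VALUES = (1, 2, 3, 4, 5, 10)


def _package_version() -> str:
    try:
        return version("typinfer")
    except PackageNotFoundError:  # pragma: no cover - editable quirk
        return "unknown"


@dataclass(frozen=True)
class ReportRequest:
    """A report selection with optional parameter overrides."""

    which: str
    alpha: float | None = None
    beta: float | None = None
    level: float = 0.95
    m_max: int = 10
    grid: tuple | None = None
    output_path: str | Path | None = None
    format: str = "csv"

    def __post_init__(self) -> None:
        if self.which not in REPORT_KINDS:
            raise InputDomainError(
                f"unknown report {self.which!r}; choose from {REPORT_KINDS}"
            )
        if self.format not in ("csv", "json"):
            raise InputDomainError(f"format must be csv or json, got {self.format!r}")

    def characteristics(self, default_alpha: float = 0.05, default_beta: float = 1.0):
        return TestCharacteristics(
            alpha=self.alpha if self.alpha is not None else default_alpha,
            beta=self.beta if self.beta is not None else default_beta,
        )


def _build_gamma_table(request: ReportRequest, sidedness: Sidedness) -> pd.DataFrame:
    tc = request.characteristics()
    return gamma_table(
        request.m_max, tc, request.level, sidedness, percent=True, rounded=True
    )


def _build_pvalue_table(request: ReportRequest, gamma0: float) -> pd.DataFrame:
    tc = request.characteristics()
    return pvalue_table(request.m_max, TypicalityNull(gamma0, tc), rounded=True)


def _build_fig1(request: ReportRequest) -> pd.DataFrame:
    grid = (
        np.asarray(request.grid, dtype=float)
        if request.grid is not None
        else np.arange(0.0, 0.50, 0.005)
    )
    return pd.DataFrame(
        {
            "omega": grid,
            "typicality": 1.0 - grid,
            "delta_1oo1": delta_curve(1, grid),
            "delta_2oo3": delta_curve(3, grid),
            "difference": delta_difference(grid),
        }
    )


def _build_fig2(request: ReportRequest) -> pd.DataFrame:
    tc = request.characteristics()
    rows = []
    for m in _FIG2_M_VALUES:
        for n in range(m + 1):
            interval = proportion_interval(
                SampleTally(n, m), request.level, Sidedness.TWO_SIDED
            )
            rows.append(
                {
                    "M": m,
                    "N": n,
                    "ratio": n / m,
                    "p_lower": interval.lower,
                    "p_upper": interval.upper,
                    "gamma_lower": gamma_from_p(interval.lower, tc),
                    "gamma_upper": gamma_from_p(interval.upper, tc),
                }
            )
    return pd.DataFrame(rows)


def _build_fig3(request: ReportRequest, sweep: str) -> pd.DataFrame:
    """gamma_c sweeps for the 2-oo-2 and 2-oo-3 tallies (one-sided bounds)."""
    frames = []
    for n, m in ((2, 2), (2, 3)):
        if sweep == "alpha":
            alphas = (
                np.asarray(request.grid, dtype=float)
                if request.grid is not None
                else np.geomspace(1e-4, 0.05, 25)
            )
            betas = request.beta if request.beta is not None else 1.0
        else:
            alphas = request.alpha if request.alpha is not None else 0.01
            betas = (
                np.asarray(request.grid, dtype=float)
                if request.grid is not None
                else np.linspace(0.5, 1.0, 26)
            )
        frame = gamma_sensitivity(
            SampleTally(n, m), alphas, betas, request.level, Sidedness.ONE_SIDED_LOWER
        )
        frame.insert(0, "M", m)
        frame.insert(0, "N", n)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _write(table: pd.DataFrame, request: ReportRequest) -> None:
    path = Path(request.output_path)
    try:
        if request.format == "csv":
            table.to_csv(path, index=table.index.name is not None)
        else:
            records = table.reset_index().to_dict(orient="records")
            cleaned = [
                {k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in rec.items()}
                for rec in records
            ]
            path.write_text(json.dumps(cleaned, indent=1))
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def run_report(request: ReportRequest) -> pd.DataFrame:
    """Build the requested report; write it if an output path is given."""
    builders = {
        "table1": lambda r: _build_gamma_table(r, Sidedness.TWO_SIDED),
        "table2": lambda r: _build_gamma_table(r, Sidedness.ONE_SIDED_LOWER),
        "table3": lambda r: _build_pvalue_table(r, 0.5),
        "table4": lambda r: _build_pvalue_table(r, 0.0),
        "fig1": _build_fig1,
        "fig2": _build_fig2,
        "fig3c": lambda r: _build_fig3(r, "alpha"),
        "fig3d": lambda r: _build_fig3(r, "beta"),
    }
    table = builders[request.which](request)
    logger.info(
        "report %s (alpha=%s beta=%s level=%s m_max=%s) typinfer %s",
        request.which,
        request.alpha,
        request.beta,
        request.level,
        request.m_max,
        _package_version(),
    )
    if request.output_path is not None:
        _write(table, request)
    return table
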