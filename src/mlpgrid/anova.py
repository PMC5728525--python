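"""Balanced main-effects ANOVA of sweep SSE, and optimal-architecture selection.

The sweeps are complete factorial designs without repetition: one SSE
observation per factor-level combination.  The variance decomposition is
therefore main-effects only — each structural factor contributes

    SS_factor = sum_levels n_level * (level mean - grand mean)^2,

the residual pools everything else (all interactions), and degrees of
freedom follow the textbook identities: L - 1 per factor, N - 1 total,
total minus the main effects for the residual.  F ratios test each factor's
mean square against the residual mean square, with upper-tail p-values from
the F distribution.  On a complete balanced design the main-effect sums of
squares are orthogonal, so no sum-of-squares "type" choice arises.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .engine import ResultsTable

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "OptimalReport",
    "BalanceError",
    "anova_main_effects",
    "f_upper_tail",
    "select_optimal",
    "factor_level_summary",
]

logger = logging.getLogger("mlpgrid")


class BalanceError(ValueError):
    """Results do not form a complete balanced factorial design."""


@dataclass(frozen=True)
class AnovaRow:
    source: str
    sum_sq: float
    df: int
    mean_sq: float | None = None
    F: float | None = None
    p: float | None = None


@dataclass(frozen=True)
class AnovaTable:
    """Ordered rows: main effects, then Residual, then Total (corrected)."""

    rows: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    @property
    def factor_rows(self) -> tuple:
        return tuple(r for r in self.rows if r.source not in ("Residual", "Total (corrected)"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Source": [r.source for r in self.rows],
                "Sum of squares": [r.sum_sq for r in self.rows],
                "Degrees of freedom": [r.df for r in self.rows],
                "Mean square": [r.mean_sq for r in self.rows],
                "Ratio-F": [r.F for r in self.rows],
                "Value-P": [r.p for r in self.rows],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class OptimalReport:
    """The SSE-minimising architecture of a sweep, laid out factor by factor."""

    design_name: str
    levels: dict                 # factor name -> chosen level
    sse: float
    row_index: int

    def to_dict(self) -> dict:
        d = {"design": self.design_name}
        d.update({k: int(v) for k, v in self.levels.items()})
        d["SSE"] = self.sse
        d["row_index"] = self.row_index
        return d


def _results_frame(results, factors=None) -> tuple[pd.DataFrame, list[str]]:
    if isinstance(results, ResultsTable):
        frame = results.to_frame()
        default_factors = list(results.factor_names)
    else:
        frame = pd.DataFrame(results)
        default_factors = [
            c for c in frame.columns if re.fullmatch(r"(NHL|AF)\d+", c)
        ]
    names = list(factors) if factors is not None else default_factors
    missing = [f for f in names if f not in frame.columns]
    if missing:
        raise ValueError(f"unknown factor(s): {missing}")
    return frame, names


def f_upper_tail(F: float, df1: int, df2: int) -> float:
    """P(X >= F) for X ~ F(df1, df2), via the regularized incomplete beta."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if F < 0:
        raise ValueError("F must be >= 0")
    # survival of the F distribution: I_{df2/(df2 + df1 F)}(df2/2, df1/2)
    return float(special.betainc(df2 / 2.0, df1 / 2.0, df2 / (df2 + df1 * F)))


def anova_main_effects(results, factors=None) -> AnovaTable:
    """Main-effects ANOVA of SSE over the named structural factors.

    ``results`` is a :class:`~mlpgrid.engine.ResultsTable` or a DataFrame
    with factor columns and an ``sse`` column.  The observations must form a
    complete balanced factorial over the named factors (equal replication of
    every full combination; the sweeps give exactly one observation each),
    every factor must have at least two levels, and no SSE may be non-finite.
    """
    frame, names = _results_frame(results, factors)
    y = frame["sse"].to_numpy(dtype=float)
    N = len(y)
    if N == 0:
        raise BalanceError("no observations")
    if not np.isfinite(y).all():
        raise BalanceError(
            f"{int((~np.isfinite(y)).sum())} non-finite SSE value(s); remove "
            "failed runs (a complete balanced design is required)"
        )
    level_counts = {}
    for f in names:
        levels = frame[f].nunique()
        if levels < 2:
            raise BalanceError(f"factor {f!r} has fewer than 2 levels")
        level_counts[f] = levels
    n_cells = int(np.prod(list(level_counts.values())))
    if N % n_cells:
        raise BalanceError(
            f"{N} observations cannot evenly fill {n_cells} factor cells"
        )
    cell_sizes = frame.groupby(names, sort=False).size()
    if len(cell_sizes) != n_cells or cell_sizes.nunique() != 1:
        raise BalanceError("design is incomplete or unbalanced across factor cells")

    grand = y.mean()
    total_ss = float(np.sum((y - grand) ** 2))
    total_df = N - 1

    rows = []
    factor_ss_sum, factor_df_sum = 0.0, 0
    for f in names:
        g = frame.groupby(f, sort=False)["sse"]
        ss = float((g.size() * (g.mean() - grand) ** 2).sum())
        df = level_counts[f] - 1
        rows.append((f, ss, df))
        factor_ss_sum += ss
        factor_df_sum += df

    resid_ss = total_ss - factor_ss_sum
    resid_df = total_df - factor_df_sum
    if resid_df <= 0:
        raise BalanceError("degenerate design: no residual degrees of freedom")
    resid_ms = resid_ss / resid_df

    out = []
    for f, ss, df in rows:
        ms = ss / df
        if resid_ms <= 0:
            warnings.warn(
                "zero residual mean square; reporting F = 0, p = 1", stacklevel=2
            )
            F_val, p_val = 0.0, 1.0
        else:
            F_val = ms / resid_ms
            p_val = f_upper_tail(F_val, df, resid_df)
        out.append(AnovaRow(f, ss, df, ms, F_val, p_val))
    out.append(AnovaRow("Residual", max(resid_ss, 0.0), resid_df, resid_ms))
    out.append(AnovaRow("Total (corrected)", total_ss, total_df))
    return AnovaTable(tuple(out))


def select_optimal(results: ResultsTable) -> OptimalReport:
    """Pick the architecture with minimal finite SSE (ties: lowest row index)."""
    finite = [r for r in results.results if np.isfinite(r.sse)]
    if not finite:
        raise ValueError("no finite SSE in results")
    best = min(finite, key=lambda r: (r.sse, r.row_index))
    levels = {}
    for i, v in enumerate(best.arch.nhl, start=1):
        levels[f"NHL{i}"] = v
    for i, v in enumerate(best.arch.af, start=1):
        levels[f"AF{i}"] = v
    return OptimalReport(
        design_name=results.design_name,
        levels=levels,
        sse=float(best.sse),
        row_index=best.row_index,
    )


def factor_level_summary(results, factor: str) -> pd.DataFrame:
    """Per-level mean/sd/min/max of SSE for one factor, in level order."""
    frame, names = _results_frame(results)
    if factor not in frame.columns:
        raise ValueError(f"unknown factor {factor!r}")
    g = frame.groupby(factor, sort=False)["sse"]
    summary = pd.DataFrame(
        {
            "level": list(g.groups.keys()),
            "mean": g.mean().to_numpy(),
            "sd": g.std(ddof=1).fillna(0.0).to_numpy(),
            "min": g.min().to_numpy(),
            "max": g.max().to_numpy(),
            "count": g.size().to_numpy(),
        }
    )
    return summary.reset_index(drop=True)
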