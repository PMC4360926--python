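"""Contingency statistics: 2×2 odds ratios with Woolf intervals.

The unadjusted odds ratio of death for a dichotomised score uses the
log-odds-ratio Wald ("Woolf") construction:

    OR = a·d / (b·c),   SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d),
    95 % CI = exp(ln OR ± 1.96·SE),   p = two-sided normal tail of ln OR / SE.

Zero cells raise by default; the Haldane–Anscombe +0.5 correction is
available but off, because a silent correction would distort published-value
reproduction.  Printed score tables report per-score mortality percentages;
``reconstruct_deaths`` converts them back to integer death counts by
rounding half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

from .cohort import Cohort
from .scoring import ScoreDistribution

__all__ = [
    "TwoByTwo",
    "AssociationResult",
    "reconstruct_deaths",
    "dichotomize",
    "odds_ratio_woolf",
    "category_mortality",
    "overall_mortality",
    "format_or_ci",
    "format_p",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure × outcome counts: a,b = deaths/survivors among exposed;
    c,d = deaths/survivors among unexposed."""

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = "exposed"
    outcome_label: str = "died"

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both exposure arms must be non-empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: Literal["woolf", "haldane_corrected"] = "woolf"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")

    def display(self) -> str:
        return (
            f"{format_or_ci(self.odds_ratio)} "
            f"({format_or_ci(self.ci_low)} to {format_or_ci(self.ci_high)})"
        )


def format_or_ci(value: float) -> str:
    """Display rounding: one decimal at ≥ 1, two significant figures below 1."""
    if value >= 1:
        return f"{value:.1f}"
    return f"{float(f'{value:.2g}'):g}"


def format_p(p: float) -> str:
    return f"{p:.3f}"


def reconstruct_deaths(n_patients: int, mortality_pct: float) -> int:
    """Integer death count from a patient count and a printed mortality %.

    Rounds half away from zero, the convention that reproduces the printed
    cohort totals.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    if not 0 <= mortality_pct <= 100:
        raise ValueError("mortality_pct must be within [0, 100]")
    deaths = int(
        (Decimal(str(mortality_pct)) * n_patients / 100).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )
    if deaths > n_patients:
        raise ValueError(
            f"reconstructed deaths ({deaths}) exceed patients ({n_patients})"
        )
    return deaths


def dichotomize(distribution: ScoreDistribution, threshold: int) -> TwoByTwo:
    """Split a score distribution at ``score ≥ threshold`` into a 2×2 table."""
    scores = [s for s, _, _ in distribution.rows]
    a = b = c = d = 0
    for s, n, deaths in distribution.rows:
        if s >= threshold:
            a += deaths
            b += n - deaths
        else:
            c += deaths
            d += n - deaths
    if threshold <= min(scores) or threshold > max(scores):
        import warnings

        warnings.warn(
            f"threshold {threshold} leaves an empty arm for the attained "
            f"score range {min(scores)}–{max(scores)}",
            RuntimeWarning,
            stacklevel=2,
        )
    return TwoByTwo(
        a=a, b=b, c=c, d=d,
        exposure_label=f"score >= {threshold}",
        outcome_label="died in hospital",
    )


def odds_ratio_woolf(
    table: TwoByTwo,
    z: float = 1.959963984540054,
    haldane: bool = False,
) -> AssociationResult:
    """Woolf (log-OR Wald) odds ratio with confidence interval and p-value.

    ``z`` defaults to the exact two-sided 95 % normal quantile; pass 1.96
    for the textbook value (the displayed results agree either way).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    method = "woolf"
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError(
                "zero cell in 2x2 table; enable haldane=True for the "
                "Haldane–Anscombe +0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "haldane_corrected"
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    p = float(2 * norm.sf(abs(log_or) / se))
    return AssociationResult(
        odds_ratio=or_, ci_low=ci_low, ci_high=ci_high, p_value=p, method=method
    )


def category_mortality(
    cohort: Cohort,
    variable_values: Sequence[float],
    intervals: Sequence[tuple[float, float]],
) -> list[dict]:
    """Observed mortality per interval of one vital.

    ``intervals`` are [low, high) pairs that must partition the observed
    values; each row reports the interval, its patient count and mortality
    percentage.
    """
    x = np.asarray(variable_values, dtype=float)
    y = np.asarray(cohort.outcomes, dtype=float)
    if len(x) != len(y):
        raise ValueError("values and cohort have different lengths")
    assigned = np.zeros(len(x), dtype=int)
    rows = []
    for lo, hi in intervals:
        sel = (x >= lo) & (x < hi)
        assigned += sel
        n = int(sel.sum())
        rows.append(
            {
                "interval": (lo, hi),
                "n": n,
                "mortality_pct": 100.0 * float(y[sel].mean()) if n else float("nan"),
            }
        )
    if np.any(assigned != 1):
        bad = np.flatnonzero(assigned != 1)[:5]
        raise ValueError(
            f"intervals do not partition the values; e.g. value(s) "
            f"{x[bad].tolist()} assigned {assigned[bad].tolist()} times"
        )
    return rows


def overall_mortality(distribution: ScoreDistribution) -> tuple[float, int]:
    """Overall mortality of a score distribution.

    Returns ``(exact_percentage, rounded_percent)``.
    """
    if distribution.n_patients == 0:
        raise ValueError("empty distribution")
    pct = 100.0 * distribution.n_deaths / distribution.n_patients
    return pct, int(round(pct))
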