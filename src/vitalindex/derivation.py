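"""Derivation of prognostic cutoffs from flexible risk curves.

The development procedure models in-hospital death against each admission
vital with a univariable logistic regression on a restricted cubic spline
basis, evaluates the fitted mortality curve on a fine grid, and segments
the vital's range into *reference* categories (model mortality at or below
the cohort average, within a small tolerance band) and *prognostic*
categories (above it).  Prognostic interval boundaries become the binary
cutoffs of an index that awards one point per abnormal vital.

Three safeguards surround the bare curve-crossing rule:

* an association screen — a likelihood-ratio test of the spline model
  against the intercept-only model (default α = 0.005 per vital, so a
  four-vital derivation on unrelated data produces any spurious category
  with probability ≈ 2 %);
* local changepoint refinement — each curve-crossing boundary is replaced
  by the two-level binomial maximum-likelihood changepoint within a window
  around it, which removes the smearing displacement a few-knot spline
  shows when the mortality step sits below the variable's median;
* category confirmation — categories are re-labelled by their *observed*
  mortality (curve first, observed category mortality second), adjacent
  same-label categories are merged, and a prognostic category must hold a
  minimum number of admissions.

The Glasgow coma score is treated categorically (≤12, 13–14, 15) rather
than splined, and collapsed to a single binary cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .cohort import Cohort
from .scoring import (
    INF,
    Band,
    Component,
    IndexDefinition,
    VARIABLE_RESOLUTION,
)
from .vitals import gcs_category

__all__ = [
    "RiskCurve",
    "Category",
    "CategorySet",
    "FitError",
    "rcs_basis",
    "default_knots",
    "fit_risk_curve",
    "derive_categories",
    "extract_cutoffs",
    "derive_gcs_component",
    "CutoffDeriver",
    "DERIVABLE_VARIABLES",
    "GRID_STEP",
]

#: Continuous vitals the spline procedure applies to.
DERIVABLE_VARIABLES = ("map", "temperature", "pulse", "resp_rate")

#: Grid step per variable.  MAP values land on thirds of a mmHg because of
#: the (SBP + 2·DBP)/3 formula; the other vitals use their measurement
#: resolution directly.
GRID_STEP = {
    "map": 1.0 / 3.0,
    "temperature": 0.1,
    "pulse": 1.0,
    "resp_rate": 1.0,
}

DEFAULT_KNOT_PERCENTILES = (5.0, 35.0, 65.0, 95.0)


class FitError(RuntimeError):
    """The risk-curve model could not be estimated."""


def default_knots(values: np.ndarray, k: int = 4) -> np.ndarray:
    """Knots at equally spaced percentiles with 5 % boundary trim.

    For the default ``k=4`` this gives the 5th/35th/65th/95th percentiles.
    """
    if k < 3:
        raise ValueError("at least 3 knots are required")
    pct = np.linspace(5.0, 95.0, k)
    knots = np.percentile(np.asarray(values, dtype=float), pct)
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "duplicate knots: the variable has too little spread for "
            f"{k} distinct percentile knots"
        )
    return knots


def rcs_basis(values: Sequence[float], knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, truncated-power form).

    For k knots t_1 < … < t_k the basis has k−1 columns: the raw values,
    then k−2 cubic terms

        C_j(x) = [(x−t_j)_+^3 − (x−t_{k−1})_+^3 (t_k−t_j)/(t_k−t_{k−1})
                  + (x−t_k)_+^3 (t_{k−1}−t_j)/(t_k−t_{k−1})] / (t_k−t_1)^2

    which vanish for x ≤ t_1 and are linear for x ≥ t_k, so the fitted
    log-odds are linear beyond the boundary knots.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("knots must be a vector of at least 3 values")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly ascending and distinct")
    x = np.asarray(values, dtype=float)
    t_last, t_pen = knots[-1], knots[-2]
    scale = (knots[-1] - knots[0]) ** 2

    def cube(u: np.ndarray) -> np.ndarray:
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for t_j in knots[:-2]:
        term = (
            cube(x - t_j)
            - cube(x - t_pen) * (t_last - t_j) / (t_last - t_pen)
            + cube(x - t_last) * (t_pen - t_j) / (t_last - t_pen)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


@dataclass(frozen=True)
class RiskCurve:
    """Model-predicted death probability over a grid of one vital's values."""

    variable: str
    grid: np.ndarray
    p_death: np.ndarray
    knots: np.ndarray
    n_obs: int
    sample_mortality: float
    lrt_pvalue: float

    def __post_init__(self) -> None:
        if np.any(self.p_death < 0) or np.any(self.p_death > 1):
            raise ValueError("predicted probabilities outside [0, 1]")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ascending")


def variable_values(cohort: Cohort, variable: str) -> np.ndarray:
    """Vector of one vital across a cohort (MAP computed from SBP/DBP)."""
    if variable == "map":
        return np.array([(r.sbp + 2.0 * r.dbp) / 3.0 for r in cohort])
    return np.array([float(getattr(r, variable)) for r in cohort])


def _grid_for(x: np.ndarray, variable: str) -> np.ndarray:
    step = GRID_STEP.get(variable, VARIABLE_RESOLUTION.get(variable, 1.0))
    lo, hi = float(np.min(x)), float(np.max(x))
    n_steps = int(round((hi - lo) / step))
    return lo + step * np.arange(n_steps + 1)


def fit_risk_curve(
    cohort: Cohort,
    variable: str,
    k_knots: int = 4,
    min_records: int = 50,
) -> RiskCurve:
    """Univariable spline-logistic risk curve of death against one vital."""
    if len(cohort) < min_records:
        raise FitError(
            f"need at least {min_records} records to fit a risk curve, "
            f"got {len(cohort)}"
        )
    x = variable_values(cohort, variable)
    y = np.asarray(cohort.outcomes, dtype=float)
    if y.min() == y.max():
        raise FitError("outcome has a single class; cannot fit a risk model")

    knots = default_knots(x, k_knots)
    design = sm.add_constant(rcs_basis(x, knots))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, design, family=sm.families.Binomial()).fit()
            null = sm.GLM(
                y, np.ones((len(y), 1)), family=sm.families.Binomial()
            ).fit()
    except Exception as exc:  # pragma: no cover - statsmodels-internal failures
        raise FitError(
            f"spline logistic fit failed for {variable!r} ({exc}); "
            "consider fewer knots"
        ) from exc
    if not np.all(np.isfinite(model.params)):
        raise FitError(
            f"non-finite coefficients for {variable!r} (separation?); "
            "consider fewer knots"
        )

    lrt = 2.0 * (model.llf - null.llf)
    pvalue = float(chi2.sf(max(lrt, 0.0), design.shape[1] - 1))

    grid = _grid_for(x, variable)
    p = np.clip(
        np.asarray(model.predict(sm.add_constant(rcs_basis(grid, knots)))),
        0.0,
        1.0,
    )
    return RiskCurve(
        variable=variable,
        grid=grid,
        p_death=p,
        knots=knots,
        n_obs=len(y),
        sample_mortality=float(y.mean()),
        lrt_pvalue=pvalue,
    )


@dataclass(frozen=True)
class Category:
    """One interval [low, high) with its observed mortality."""

    low: float
    high: float
    n: int
    mortality: float
    is_reference: bool


@dataclass(frozen=True)
class CategorySet:
    """Reference/prognostic partition of one vital's observed range."""

    variable: str
    categories: tuple[Category, ...]
    sample_mortality: float
    screened_out: bool = False  # no association found; single reference category

    @property
    def prognostic_intervals(self) -> tuple[tuple[float, float], ...]:
        return tuple(
            (c.low, c.high) for c in self.categories if not c.is_reference
        )

    @property
    def is_flat(self) -> bool:
        return len(self.prognostic_intervals) == 0


def _changepoint(
    x: np.ndarray,
    y: np.ndarray,
    boundary: float,
    candidate_step: float,
    window: float,
) -> float:
    """Two-level binomial ML changepoint near ``boundary``.

    Scans candidate cutpoints within ``±window`` of the spline crossing,
    using records within twice the window, and returns the cutpoint whose
    two-proportion model has maximal likelihood.  Falls back to the input
    boundary when a side has too few records.
    """
    cands = boundary + candidate_step * np.arange(
        -round(window / candidate_step), round(window / candidate_step) + 1
    )
    sel = (x >= boundary - 2 * window) & (x <= boundary + 2 * window)
    xs, ys = x[sel], y[sel]
    best_ll, best_c = -np.inf, boundary
    for c in cands:
        upper = xs >= c
        n1, n0 = int(upper.sum()), int((~upper).sum())
        if n1 < 5 or n0 < 5:
            continue
        ll = 0.0
        for deaths, n in ((ys[upper].sum(), n1), (ys[~upper].sum(), n0)):
            p = deaths / n
            if 0.0 < p < 1.0:
                ll += deaths * np.log(p) + (n - deaths) * np.log(1.0 - p)
        if ll > best_ll:
            best_ll, best_c = ll, float(c)
    return best_c


def derive_categories(
    curve: RiskCurve,
    cohort: Cohort,
    tolerance_band: float = 0.02,
    screen_alpha: float = 0.005,
    min_support: int = 20,
    refine_window_units: float = 15.0,
    refine: bool = True,
) -> CategorySet:
    """Segment one vital into reference and prognostic categories.

    The fitted curve is compared against the cohort mortality plus the
    "about average" tolerance band (default 2 percentage points).  Curve
    crossings give candidate boundaries, refined by a local changepoint;
    the resulting categories are labelled by observed mortality, merged,
    and prognostic categories must hold ``min_support`` admissions.
    """
    x = variable_values(cohort, curve.variable)
    y = np.asarray(cohort.outcomes, dtype=float)
    mbar = float(y.mean())
    threshold = mbar + tolerance_band

    def single_reference(screened: bool) -> CategorySet:
        return CategorySet(
            variable=curve.variable,
            categories=(
                Category(
                    low=float(x.min()),
                    high=float(x.max()) + 1e-9,
                    n=len(x),
                    mortality=mbar,
                    is_reference=True,
                ),
            ),
            sample_mortality=mbar,
            screened_out=screened,
        )

    if curve.lrt_pvalue >= screen_alpha:
        return single_reference(screened=True)

    above = curve.p_death > threshold
    if not above.any():
        return single_reference(screened=False)

    flips = np.flatnonzero(above[1:] != above[:-1])
    boundaries = [float(curve.grid[i + 1]) for i in flips]

    resolution = VARIABLE_RESOLUTION.get(curve.variable, 1.0)
    step = float(np.min(np.diff(curve.grid))) if len(curve.grid) > 1 else resolution
    if refine:
        window = refine_window_units * resolution
        boundaries = [_changepoint(x, y, b, step, window) for b in boundaries]
    boundaries = sorted(
        {b for b in boundaries if x.min() < b <= x.max()}
    )

    edges = [float(x.min())] + boundaries + [float(x.max()) + 1e-9]
    raw: list[list[float]] = []  # [low, high, n, mortality]
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (x >= lo) & (x < hi)
        n = int(sel.sum())
        if n == 0:
            continue
        raw.append([lo, hi, n, float(y[sel].mean())])

    def absorb(i: int, j: int) -> None:
        lo_i, hi_i, n_i, m_i = raw[i]
        lo_j, hi_j, n_j, m_j = raw[j]
        n = n_i + n_j
        raw[min(i, j)] = [
            min(lo_i, lo_j), max(hi_i, hi_j), n, (m_i * n_i + m_j * n_j) / n,
        ]
        del raw[max(i, j)]

    # categories too small to characterise join the neighbour whose
    # mortality is closest to theirs
    while len(raw) > 1 and min(c[2] for c in raw) < min_support:
        i = min(range(len(raw)), key=lambda k: raw[k][2])
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < len(raw)]
        j = min(neighbours, key=lambda k: abs(raw[k][3] - raw[i][3]))
        absorb(i, j)

    cats = [
        Category(low=lo, high=hi, n=n, mortality=m, is_reference=not m > threshold)
        for lo, hi, n, m in raw
    ]

    # merge adjacent categories with the same label
    merged: list[Category] = []
    for c in cats:
        if merged and merged[-1].is_reference == c.is_reference:
            prev = merged[-1]
            n = prev.n + c.n
            merged[-1] = Category(
                low=prev.low,
                high=c.high,
                n=n,
                mortality=(prev.mortality * prev.n + c.mortality * c.n) / n,
                is_reference=c.is_reference,
            )
        else:
            merged.append(c)

    if all(c.is_reference for c in merged):
        return single_reference(screened=False)
    return CategorySet(
        variable=curve.variable,
        categories=tuple(merged),
        sample_mortality=mbar,
    )


def _round_to(value: float, resolution: float) -> float:
    r = round(value / resolution) * resolution
    # keep temperature cutoffs tidy at one decimal
    return round(r, 10)


def extract_cutoffs(
    category_sets: Sequence[CategorySet],
    resolution: Mapping[str, float] | None = None,
) -> IndexDefinition:
    """Binary scoring bands from per-vital category partitions.

    Each prognostic interval scores 1, reference values score 0; interval
    boundaries are rounded to the vital's measurement resolution.  Vitals
    whose partition is a single reference category are omitted.
    """
    resolution = dict(resolution or VARIABLE_RESOLUTION)
    components: list[Component] = []
    for cs in category_sets:
        if cs.is_flat:
            continue
        res = resolution.get(cs.variable, 1.0)
        lo_data = cs.categories[0].low
        hi_data = cs.categories[-1].high
        bands: list[Band] = []
        prev_edge = -INF
        for cat in cs.categories:
            lo = -INF if cat.low <= lo_data else _round_to(cat.low, res)
            hi = INF if cat.high >= hi_data else _round_to(cat.high, res)
            bands.append(
                Band(
                    low=prev_edge,
                    high=hi,
                    points=0 if cat.is_reference else 1,
                    low_closed=True,
                    high_closed=False,
                )
            )
            prev_edge = hi
        components.append(Component(variable=cs.variable, bands=tuple(bands)))
    return IndexDefinition(name="derived", components=tuple(components))


def derive_gcs_component(
    cohort: Cohort,
    tolerance_band: float = 0.02,
    min_support: int = 10,
    screen_alpha: float = 0.005,
) -> Component | None:
    """Binary GCS cutoff from the three-level categorisation.

    Mortality is tabulated at GCS 15, 13–14 and ≤12; contiguous depressed
    levels with mortality above the cohort average (plus the tolerance
    band) collapse into a single "≤ cutoff" scoring band.  As with the
    splined vitals, an association screen guards segmentation: depressed
    consciousness (GCS ≤ 14) must be associated with death at the
    ``screen_alpha`` level (two-proportion chi-square).  Returns ``None``
    when no level is prognostic.
    """
    y = np.asarray(cohort.outcomes, dtype=float)
    gcs = np.array([r.gcs for r in cohort])
    threshold = float(y.mean()) + tolerance_band

    depressed = gcs <= 14
    if depressed.sum() >= 5 and (~depressed).sum() >= 5:
        from scipy.stats import chi2_contingency

        table = np.array(
            [
                [y[depressed].sum(), (~y.astype(bool))[depressed].sum()],
                [y[~depressed].sum(), (~y.astype(bool))[~depressed].sum()],
            ]
        )
        if np.all(table.sum(axis=1) > 0) and np.all(table.sum(axis=0) > 0):
            _, pvalue, _, _ = chi2_contingency(table, correction=False)
            if pvalue >= screen_alpha:
                return None

    def level_stats(mask: np.ndarray) -> tuple[int, float]:
        n = int(mask.sum())
        return n, (float(y[mask].mean()) if n else 0.0)

    n12, m12 = level_stats(gcs <= 12)
    n1314, m1314 = level_stats((gcs >= 13) & (gcs <= 14))

    prog_1314 = n1314 >= min_support and m1314 > threshold
    prog_12 = n12 >= min_support and m12 > threshold
    if prog_1314 and prog_12:
        cutoff = 14.0
    elif prog_12:
        cutoff = 12.0
    elif prog_1314:
        # depressed-but-not-lowest alone: still collapse to ≤14 (monotone rule)
        cutoff = 14.0
    else:
        return None
    return Component(
        "gcs",
        (
            Band(-INF, cutoff + 1.0, 1, low_closed=False, high_closed=False),
            Band(cutoff + 1.0, INF, 0, low_closed=True, high_closed=False),
        ),
    )


class CutoffDeriver:
    """Scikit-learn style estimator deriving a binary prognostic index.

    ``fit`` takes a vitals data frame (columns ``sbp``, ``dbp``, ``pulse``,
    ``resp_rate``, ``temperature``, ``gcs``; ``map`` is computed) and a
    binary outcome vector, runs the spline/segmentation procedure per
    vital, and exposes the result as ``index_definition_`` along with the
    per-vital ``risk_curves_`` and ``category_sets_``.  ``transform``
    scores new data with the derived index.

    Parameters
    ----------
    variables : continuous vitals to derive on.
    k_knots : spline knots (default 4 at the 5/35/65/95th percentiles).
    tolerance_band : "about average" margin on the probability scale.
    screen_alpha : per-vital likelihood-ratio screen level.
    min_support : minimum admissions in a prognostic category.
    refine_window_units : changepoint search half-window, in resolution units.
    include_gcs : also derive the categorical GCS cutoff.
    min_records : minimum cohort size for any fit.
    """

    def __init__(
        self,
        variables: Sequence[str] = DERIVABLE_VARIABLES,
        k_knots: int = 4,
        tolerance_band: float = 0.02,
        screen_alpha: float = 0.005,
        min_support: int = 20,
        refine_window_units: float = 15.0,
        refine: bool = True,
        include_gcs: bool = True,
        min_records: int = 50,
    ):
        self.variables = tuple(variables)
        self.k_knots = k_knots
        self.tolerance_band = tolerance_band
        self.screen_alpha = screen_alpha
        self.min_support = min_support
        self.refine_window_units = refine_window_units
        self.refine = refine
        self.include_gcs = include_gcs
        self.min_records = min_records

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "variables", "k_knots", "tolerance_band", "screen_alpha",
                "min_support", "refine_window_units", "refine",
                "include_gcs", "min_records",
            )
        }

    def set_params(self, **params) -> "CutoffDeriver":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------

    def fit_cohort(self, cohort: Cohort) -> "CutoffDeriver":
        self.risk_curves_: dict[str, RiskCurve] = {}
        self.category_sets_: dict[str, CategorySet] = {}
        for v in self.variables:
            curve = fit_risk_curve(
                cohort, v, k_knots=self.k_knots, min_records=self.min_records
            )
            self.risk_curves_[v] = curve
            self.category_sets_[v] = derive_categories(
                curve,
                cohort,
                tolerance_band=self.tolerance_band,
                screen_alpha=self.screen_alpha,
                min_support=self.min_support,
                refine_window_units=self.refine_window_units,
                refine=self.refine,
            )
        definition = extract_cutoffs(list(self.category_sets_.values()))
        components = list(definition.components)
        self.gcs_component_ = None
        if self.include_gcs:
            self.gcs_component_ = derive_gcs_component(
                cohort, tolerance_band=self.tolerance_band
            )
            if self.gcs_component_ is not None:
                components.append(self.gcs_component_)
        self.index_definition_ = IndexDefinition(
            name="derived", components=tuple(components)
        )
        self.sample_mortality_ = float(np.mean(cohort.outcomes))
        self.n_obs_ = len(cohort)
        return self

    def fit(self, X: pd.DataFrame, y: Sequence[int]) -> "CutoffDeriver":
        from .cohort import Cohort, PatientRecord

        frame = X.reset_index(drop=True)
        y = np.asarray(y).astype(bool)
        if len(frame) != len(y):
            raise ValueError("X and y have different lengths")
        records = []
        for i, row in frame.iterrows():
            records.append(
                PatientRecord(
                    patient_id=f"r{i}",
                    sbp=float(row["sbp"]),
                    dbp=float(row["dbp"]),
                    pulse=float(row["pulse"]),
                    resp_rate=float(row["resp_rate"]),
                    temperature=float(row["temperature"]),
                    gcs=int(row["gcs"]),
                    suspected_infection=True,
                    died_in_hospital=bool(y[i]),
                )
            )
        return self.fit_cohort(Cohort(label="fit", records=records))

    def transform(self, X: pd.DataFrame) -> pd.Series:
        from .scoring import IndexScorer

        if not hasattr(self, "index_definition_"):
            raise RuntimeError("CutoffDeriver is not fitted")
        return IndexScorer(self.index_definition_).fit().transform(X)

    def fit_transform(self, X: pd.DataFrame, y: Sequence[int]) -> pd.Series:
        return self.fit(X, y).transform(X)
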