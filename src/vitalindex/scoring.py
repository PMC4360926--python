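"""Prognostic index definitions and scoring.

Two fixed indexes ship with the package:

* the reduced-segmentation index — one point each for respiratory rate
  ≥ 30/min, pulse ≥ 100/min, MAP ≥ 110 or < 70 mmHg, temperature ≥ 38.6 or
  < 35.6 °C, and GCS ≤ 14 (maximum 5);
* the Modified Early Warning Score (MEWS) comparator, with its heavier
  segmentation (maximum 14 under the banding implemented here).

An :class:`IndexDefinition` maps, per variable, disjoint covering intervals
to integer points.  MAP is always computed from SBP/DBP on the fly so a
record can never carry an inconsistent pressure triple.  The MEWS source
enumeration has touching printed bands ("70 to 80", "80 to 100"); shared
boundaries are resolved to the higher-severity band, and pulse < 40 —
absent from the enumeration — scores 0 and raises a warning flag.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import Cohort, PatientRecord
from .vitals import mean_arterial_pressure

__all__ = [
    "Band",
    "Component",
    "IndexDefinition",
    "ScoreDistribution",
    "ScoringError",
    "proposed_index_definition",
    "mews_definition",
    "score",
    "score_cohort",
    "score_distribution",
    "IndexScorer",
]

INF = math.inf

#: Variables an index may reference, with the measurement resolution used
#: for cutoff rounding and display.
VARIABLE_RESOLUTION = {
    "resp_rate": 1.0,
    "pulse": 1.0,
    "map": 1.0,
    "temperature": 0.1,
    "gcs": 1.0,
    "sbp": 1.0,
}

#: Valid domain per variable (used by the completeness invariant).
VARIABLE_DOMAIN = {
    "resp_rate": (0.0, 200.0),
    "pulse": (0.0, 400.0),
    "map": (0.0, 400.0),
    "temperature": (25.0, 45.0),
    "gcs": (3.0, 15.0),
    "sbp": (0.0, 400.0),
}


class ScoringError(ValueError):
    """A record cannot be scored against an index definition."""


@dataclass(frozen=True)
class Band:
    """A numeric interval mapped to a point value.

    ``low``/``high`` may be infinite; each bound may be closed or open.
    """

    low: float
    high: float
    points: int
    low_closed: bool = True
    high_closed: bool = False
    flag: str | None = None

    def contains(self, value: float) -> bool:
        above = value > self.low or (self.low_closed and value == self.low)
        below = value < self.high or (self.high_closed and value == self.high)
        return above and below

    def describe(self) -> str:
        lo = "[" if self.low_closed else "("
        hi = "]" if self.high_closed else ")"
        return f"{lo}{self.low}, {self.high}{hi} -> {self.points}"


@dataclass(frozen=True)
class Component:
    """All bands of one variable; the bands partition its valid domain."""

    variable: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if self.variable not in VARIABLE_RESOLUTION:
            raise ValueError(f"unknown variable {self.variable!r}")

    def points_for(self, value: float) -> int:
        matches = [b for b in self.bands if b.contains(value)]
        if len(matches) != 1:
            raise ScoringError(
                f"value {value} of {self.variable!r} matches "
                f"{len(matches)} bands (must be exactly 1)"
            )
        band = matches[0]
        if band.flag:
            warnings.warn(
                f"{self.variable}={value}: {band.flag}", RuntimeWarning, stacklevel=3
            )
        return band.points

    @property
    def max_points(self) -> int:
        return max(b.points for b in self.bands)


@dataclass(frozen=True)
class IndexDefinition:
    """A named set of scored components."""

    name: str
    components: tuple[Component, ...]

    @property
    def max_score(self) -> int:
        return sum(c.max_points for c in self.components)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(c.variable for c in self.components)

    def component(self, variable: str) -> Component:
        for c in self.components:
            if c.variable == variable:
                return c
        raise KeyError(variable)

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "components": [
                {
                    "variable": c.variable,
                    "bands": [
                        {
                            "low": None if math.isinf(b.low) else b.low,
                            "high": None if math.isinf(b.high) else b.high,
                            "points": b.points,
                            "low_closed": b.low_closed,
                            "high_closed": b.high_closed,
                            **({"flag": b.flag} if b.flag else {}),
                        }
                        for b in c.bands
                    ],
                }
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "IndexDefinition":
        comps = []
        for c in data["components"]:
            bands = tuple(
                Band(
                    low=-INF if b["low"] is None else float(b["low"]),
                    high=INF if b["high"] is None else float(b["high"]),
                    points=int(b["points"]),
                    low_closed=bool(b.get("low_closed", True)),
                    high_closed=bool(b.get("high_closed", False)),
                    flag=b.get("flag"),
                )
                for b in c["bands"]
            )
            comps.append(Component(variable=c["variable"], bands=bands))
        return cls(name=data["name"], components=tuple(comps))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "IndexDefinition":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _abnormal_outside(variable: str, low: float | None, high: float | None) -> Component:
    """One point outside [low, high); zero inside.  ``None`` disables a side."""
    bands = []
    lo = -INF if low is None else low
    hi = INF if high is None else high
    if low is not None:
        bands.append(Band(-INF, low, 1, low_closed=False, high_closed=False))
    bands.append(Band(lo, hi, 0, low_closed=True, high_closed=False))
    if high is not None:
        bands.append(Band(hi, INF, 1, low_closed=True, high_closed=False))
    return Component(variable=variable, bands=tuple(bands))


def proposed_index_definition() -> IndexDefinition:
    """The reduced-segmentation admission-vitals index (maximum score 5).

    One point for each of: respiratory rate ≥ 30, pulse ≥ 100, MAP ≥ 110 or
    < 70, temperature ≥ 38.6 or < 35.6 °C, GCS ≤ 14; zero otherwise.
    """
    return IndexDefinition(
        name="proposed",
        components=(
            _abnormal_outside("resp_rate", None, 30.0),
            _abnormal_outside("pulse", None, 100.0),
            _abnormal_outside("map", 70.0, 110.0),
            _abnormal_outside("temperature", 35.6, 38.6),
            Component(
                "gcs",
                (
                    Band(-INF, 15.0, 1, low_closed=False, high_closed=False),
                    Band(15.0, INF, 0, low_closed=True, high_closed=False),
                ),
            ),
        ),
    )


def mews_definition() -> IndexDefinition:
    """The Modified Early Warning Score comparator (maximum total 14).

    Bands follow the classic enumeration: 3 points for SBP < 70, pulse
    ≥ 130, respiratory rate ≥ 30, GCS ≤ 8; 2 points for SBP 70–80 or ≥ 200,
    pulse 111–129, respiratory rate < 9 or 21–29, temperature < 35 or
    ≥ 38.5, GCS 9–13; 1 point for SBP 80–100, pulse 40–50 or 101–110,
    respiratory rate 16–20, GCS 14.  Shared printed boundaries go to the
    higher-severity band; pulse < 40 is unscored in the enumeration and is
    implemented as 0 points with a warning flag.
    """
    return IndexDefinition(
        name="mews",
        components=(
            Component(
                "sbp",
                (
                    Band(-INF, 70.0, 3, low_closed=False, high_closed=False),
                    Band(70.0, 80.0, 2, low_closed=True, high_closed=True),
                    Band(80.0, 100.0, 1, low_closed=False, high_closed=True),
                    Band(100.0, 200.0, 0, low_closed=False, high_closed=False),
                    Band(200.0, INF, 2, low_closed=True, high_closed=False),
                ),
            ),
            Component(
                "pulse",
                (
                    Band(
                        -INF, 40.0, 0,
                        low_closed=False, high_closed=False,
                        flag="pulse below 40 is unscored in the MEWS band enumeration",
                    ),
                    Band(40.0, 50.0, 1, low_closed=True, high_closed=True),
                    Band(50.0, 101.0, 0, low_closed=False, high_closed=False),
                    Band(101.0, 111.0, 1, low_closed=True, high_closed=False),
                    Band(111.0, 130.0, 2, low_closed=True, high_closed=False),
                    Band(130.0, INF, 3, low_closed=True, high_closed=False),
                ),
            ),
            Component(
                "resp_rate",
                (
                    Band(-INF, 9.0, 2, low_closed=False, high_closed=False),
                    Band(9.0, 16.0, 0, low_closed=True, high_closed=False),
                    Band(16.0, 21.0, 1, low_closed=True, high_closed=False),
                    Band(21.0, 30.0, 2, low_closed=True, high_closed=False),
                    Band(30.0, INF, 3, low_closed=True, high_closed=False),
                ),
            ),
            Component(
                "temperature",
                (
                    Band(-INF, 35.0, 2, low_closed=False, high_closed=False),
                    Band(35.0, 38.5, 0, low_closed=True, high_closed=False),
                    Band(38.5, INF, 2, low_closed=True, high_closed=False),
                ),
            ),
            Component(
                "gcs",
                (
                    Band(-INF, 9.0, 3, low_closed=False, high_closed=False),
                    Band(9.0, 14.0, 2, low_closed=True, high_closed=False),
                    Band(14.0, 15.0, 1, low_closed=True, high_closed=False),
                    Band(15.0, INF, 0, low_closed=True, high_closed=False),
                ),
            ),
        ),
    )


def _variable_value(record: PatientRecord, variable: str) -> float:
    if variable == "map":
        return mean_arterial_pressure(record.sbp, record.dbp)
    value = getattr(record, variable, None)
    if value is None:
        raise ScoringError(
            f"record {record.patient_id!r} is missing variable {variable!r}"
        )
    return float(value)


def score(record: PatientRecord, definition: IndexDefinition) -> int:
    """Total index score of one record (sum of component points)."""
    return sum(
        c.points_for(_variable_value(record, c.variable))
        for c in definition.components
    )


def score_cohort(cohort: Cohort, definition: IndexDefinition) -> pd.DataFrame:
    """Per-record scores with outcome, as a data frame."""
    rows = []
    for r in cohort:
        try:
            s = score(r, definition)
        except ScoringError as exc:
            raise ScoringError(f"patient {r.patient_id!r}: {exc}") from None
        rows.append(
            {"patient_id": r.patient_id, "score": s, "died": r.died_in_hospital}
        )
    return pd.DataFrame(rows, columns=["patient_id", "score", "died"])


@dataclass(frozen=True)
class ScoreDistribution:
    """Patient and death counts at each attained score."""

    label: str
    rows: tuple[tuple[int, int, int], ...]  # (score, n_patients, n_deaths)

    def __post_init__(self) -> None:
        for s, n, d in self.rows:
            if not 0 <= d <= n:
                raise ValueError(f"score {s}: deaths {d} outside [0, {n}]")

    @property
    def n_patients(self) -> int:
        return sum(n for _, n, _ in self.rows)

    @property
    def n_deaths(self) -> int:
        return sum(d for _, _, d in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows), columns=["score", "n_patients", "n_deaths"]
        )


def score_distribution(
    cohort: Cohort, definition: IndexDefinition
) -> ScoreDistribution:
    """Tabulate patients and deaths at each attained score."""
    if len(cohort) == 0:
        raise ValueError("cannot tabulate an empty cohort")
    scored = score_cohort(cohort, definition)
    grouped = scored.groupby("score")["died"].agg(["count", "sum"]).sort_index()
    rows = tuple(
        (int(s), int(row["count"]), int(row["sum"]))
        for s, row in grouped.iterrows()
    )
    return ScoreDistribution(label=cohort.label, rows=rows)


class IndexScorer:
    """Scikit-learn style transformer applying a fixed index definition.

    ``transform`` accepts a data frame with the cohort columns (``map`` is
    computed from ``sbp``/``dbp``) and returns the integer scores.  The
    estimator is stateless; ``fit`` only validates the definition.
    """

    def __init__(self, definition: IndexDefinition | None = None):
        self.definition = definition

    # BaseEstimator-compatible param plumbing without the sklearn import.
    def get_params(self, deep: bool = True) -> dict:
        return {"definition": self.definition}

    def set_params(self, **params) -> "IndexScorer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "IndexScorer":
        self.definition_ = (
            self.definition if self.definition is not None
            else proposed_index_definition()
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "definition_"):
            self.fit()
        defn = self.definition_
        frame = X.copy()
        if "map" not in frame.columns and {"sbp", "dbp"} <= set(frame.columns):
            frame["map"] = (frame["sbp"] + 2 * frame["dbp"]) / 3.0
        missing = [v for v in defn.variables if v not in frame.columns]
        if missing:
            raise ScoringError(f"input is missing variable(s) {missing}")
        totals = []
        for _, row in frame.iterrows():
            totals.append(
                sum(
                    defn.component(v).points_for(float(row[v]))
                    for v in defn.variables
                )
            )
        return pd.Series(totals, index=frame.index, name=f"{defn.name}_score")

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X, y).transform(X)
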