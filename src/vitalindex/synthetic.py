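"""Seedable synthetic admission-vitals cohorts with known risk structure.

The generator emulates the development cohort of the original study in two
respects:

* **marginals** — each vital is drawn from a simple parametric family
  (log-normal for pulse, respiratory rate, pressures, white cells,
  platelets and age; normal for axillary temperature; categorical for the
  Glasgow coma score) whose median matches the published cohort median,
  with spread consistent with the published inter-quartile range;
* **risk shape** — in-hospital death follows a logistic model whose
  log-odds jump by a *threshold effect* when a vital crosses a planted
  cutoff (respiratory rate ≥ 30, pulse ≥ 100, MAP outside 70–110,
  temperature outside 35.6–38.6 °C, GCS ≤ 14), with mild additional slope
  beyond the respiratory-rate, pulse and temperature thresholds.  The
  intercept is calibrated by bisection so the expected mortality matches a
  target (default 23 %).

A threshold effect — rather than a smooth hinge or parabola — is used
deliberately: it pins the point where the vital's *marginal* mortality
curve crosses the cohort average exactly at the planted cutoff, whatever
the share of patients beyond it.  A smooth monotone contribution places
that crossing where the contribution equals its population mean, which for
pulse (median 108, cutoff 100) can never be at 100; planted cutoffs would
then be unrecoverable by construction rather than because of any defect in
the derivation.  Effect amplitudes (1.0–1.6 log-odds) are larger than the
contrasts reported in the study so each cutoff is statistically
identifiable to the index's resolution at the default cohort size.

The module also rebuilds per-patient (score, outcome) fixtures from the
published per-score mortality tables of the two cohorts.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.special import expit

from .association import reconstruct_deaths
from .cohort import Cohort, PatientRecord

__all__ = [
    "Marginal",
    "ThresholdEffect",
    "BandEffect",
    "GeneratorConfig",
    "generate_cohort",
    "table1_default_marginals",
    "reconstruct_from_score_table",
    "DEVELOPMENT_SCORE_TABLE",
    "VALIDATION_SCORE_TABLE",
]

#: Per-score rows (score, n_patients, mortality %) of the proposed index as
#: published for the original development cohort (n = 167, 23 % mortality).
DEVELOPMENT_SCORE_TABLE: tuple[tuple[int, int, float], ...] = (
    (0, 28, 11.0),
    (1, 32, 6.3),
    (2, 57, 25.0),
    (3, 36, 36.0),
    (4, 12, 42.0),
    (5, 2, 100.0),
)

#: Same for the original validation cohort (n = 150, 30 % mortality).
VALIDATION_SCORE_TABLE: tuple[tuple[int, int, float], ...] = (
    (0, 3, 33.0),
    (1, 26, 27.0),
    (2, 38, 16.0),
    (3, 59, 34.0),
    (4, 18, 33.0),
    (5, 6, 83.0),
)


class Marginal(BaseModel):
    """Log-normal (default) or normal marginal with a clinical resolution."""

    model_config = ConfigDict(frozen=True)

    median: float = Field(gt=0)
    sigma: float = Field(gt=0)  # log-scale SD (log-normal) or SD (normal)
    family: str = "lognormal"  # "lognormal" | "normal"
    resolution: float = 1.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "lognormal":
            values = np.exp(rng.normal(math.log(self.median), self.sigma, n))
        elif self.family == "normal":
            values = rng.normal(self.median, self.sigma, n)
        else:  # pragma: no cover
            raise ValueError(f"unknown family {self.family!r}")
        decimals = max(0, int(round(-math.log10(self.resolution))))
        return np.round(values / self.resolution) * self.resolution if decimals == 0 \
            else np.round(values, decimals)


class ThresholdEffect(BaseModel):
    """Log-odds step at ``threshold`` plus optional slope beyond it."""

    model_config = ConfigDict(frozen=True)

    threshold: float
    amplitude: float = Field(ge=0)
    slope: float = Field(default=0.0, ge=0)
    slope_cap: float = Field(default=math.inf, gt=0)

    def log_odds(self, x: np.ndarray) -> np.ndarray:
        excess = np.minimum(np.maximum(x - self.threshold, 0.0), self.slope_cap)
        return self.amplitude * (x >= self.threshold) + self.slope * excess


class BandEffect(BaseModel):
    """Log-odds step outside a reference band plus optional outward slope."""

    model_config = ConfigDict(frozen=True)

    low: float
    high: float
    amplitude: float = Field(ge=0)
    slope: float = Field(default=0.0, ge=0)

    def log_odds(self, x: np.ndarray) -> np.ndarray:
        outside = (x < self.low) | (x >= self.high)
        dist = np.where(
            x < self.low, self.low - x, np.where(x >= self.high, x - self.high, 0.0)
        )
        return outside * (self.amplitude + self.slope * dist**2)


class GeneratorConfig(BaseModel):
    """Cohort size, seed, marginals and planted risk structure."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(default=5000, gt=0)
    seed: int = 0
    target_mortality: float = Field(default=0.23, gt=0, lt=1)

    pulse: Marginal = Marginal(median=108, sigma=0.2132)
    resp_rate: Marginal = Marginal(median=28, sigma=0.2777)
    sbp: Marginal = Marginal(median=100, sigma=0.28)
    dbp: Marginal = Marginal(median=60, sigma=0.32)
    sbp_dbp_corr: float = Field(default=0.6, ge=0, lt=1)
    temperature: Marginal = Marginal(
        median=37.0, sigma=1.33, family="normal", resolution=0.1
    )
    wbc: Marginal = Marginal(median=4.7, sigma=0.616, resolution=0.1)
    platelets: Marginal = Marginal(median=160, sigma=0.557)
    age: Marginal = Marginal(median=38, sigma=0.50)
    male_fraction: float = Field(default=0.53, ge=0, le=1)
    #: probability mass on GCS 15 / 13–14 / ≤12
    gcs_probs: tuple[float, float, float] = (0.80, 0.14, 0.06)

    resp_rate_effect: ThresholdEffect = ThresholdEffect(
        threshold=30.0, amplitude=1.2, slope=0.04
    )
    pulse_effect: ThresholdEffect = ThresholdEffect(
        threshold=100.0, amplitude=1.0, slope=0.01, slope_cap=30.0
    )
    map_effect: BandEffect = BandEffect(low=70.0, high=110.0, amplitude=1.6)
    temperature_effect: BandEffect = BandEffect(
        low=35.6, high=38.6, amplitude=1.2, slope=0.15
    )
    gcs_effect: float = Field(default=0.9, ge=0)  # log-odds for GCS ≤ 14

    def null_risk(self) -> "GeneratorConfig":
        """Copy of the config with all vital effects removed (null model)."""
        return self.model_copy(
            update={
                "resp_rate_effect": ThresholdEffect(threshold=30.0, amplitude=0.0),
                "pulse_effect": ThresholdEffect(threshold=100.0, amplitude=0.0),
                "map_effect": BandEffect(low=70.0, high=110.0, amplitude=0.0),
                "temperature_effect": BandEffect(low=35.6, high=38.6, amplitude=0.0),
                "gcs_effect": 0.0,
            }
        )

    @property
    def planted_cutoffs(self) -> dict[str, tuple[float, ...]]:
        return {
            "resp_rate": (self.resp_rate_effect.threshold,),
            "pulse": (self.pulse_effect.threshold,),
            "map": (self.map_effect.low, self.map_effect.high),
            "temperature": (
                self.temperature_effect.low,
                self.temperature_effect.high,
            ),
        }


def table1_default_marginals() -> dict[str, Marginal]:
    """Default marginal parameters, keyed by vital."""
    cfg = GeneratorConfig()
    return {
        "pulse": cfg.pulse,
        "resp_rate": cfg.resp_rate,
        "sbp": cfg.sbp,
        "dbp": cfg.dbp,
        "temperature": cfg.temperature,
        "wbc": cfg.wbc,
        "platelets": cfg.platelets,
        "age": cfg.age,
    }


def _draw_gcs(rng: np.random.Generator, n: int, probs: Sequence[float]) -> np.ndarray:
    level = rng.choice(3, size=n, p=np.asarray(probs, dtype=float))
    gcs = np.full(n, 15, dtype=int)
    mid = level == 1
    gcs[mid] = rng.integers(13, 15, size=int(mid.sum()))  # 13 or 14
    low = level == 2
    gcs[low] = rng.integers(3, 13, size=int(low.sum()))  # 3..12
    return gcs


def _calibrate_intercept(
    log_odds: np.ndarray, target: float, tol: float = 1e-6
) -> float:
    """Bisect the intercept so mean expit(b0 + log_odds) hits the target."""
    lo, hi = -30.0, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        realized = float(expit(mid + log_odds).mean())
        if abs(realized - target) < tol:
            return mid
        if realized > target:
            hi = mid
        else:
            lo = mid
    raise RuntimeError(
        f"intercept calibration did not converge (target {target}, "
        f"last realized {realized})"
    )


def generate_cohort(
    config: GeneratorConfig | None = None,
    label: str = "synthetic",
    **overrides,
) -> Cohort:
    """Draw a synthetic cohort; deterministic given the config seed.

    ``overrides`` are convenience keyword updates of the config, e.g.
    ``generate_cohort(n=2000, seed=7)``.
    """
    cfg = (config or GeneratorConfig()).model_copy(update=overrides) \
        if overrides else (config or GeneratorConfig())
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    pulse = np.maximum(cfg.pulse.draw(rng, n), 1)
    resp = np.maximum(cfg.resp_rate.draw(rng, n), 1)
    z = rng.multivariate_normal(
        [0.0, 0.0],
        [[1.0, cfg.sbp_dbp_corr], [cfg.sbp_dbp_corr, 1.0]],
        size=n,
    )
    sbp = np.maximum(np.round(np.exp(math.log(cfg.sbp.median) + cfg.sbp.sigma * z[:, 0])), 2)
    dbp = np.maximum(np.round(np.exp(math.log(cfg.dbp.median) + cfg.dbp.sigma * z[:, 1])), 1)
    clash = dbp >= sbp
    dbp[clash] = sbp[clash] - 1  # physiologic ordering enforced
    mapv = (sbp + 2.0 * dbp) / 3.0
    temp = np.clip(cfg.temperature.draw(rng, n), 25.0, 45.0)
    gcs = _draw_gcs(rng, n, cfg.gcs_probs)
    wbc = cfg.wbc.draw(rng, n)
    platelets = np.maximum(cfg.platelets.draw(rng, n), 1)
    age = np.clip(cfg.age.draw(rng, n), 15, 105).astype(int)
    male = rng.random(n) < cfg.male_fraction

    log_odds = (
        cfg.resp_rate_effect.log_odds(resp)
        + cfg.pulse_effect.log_odds(pulse)
        + cfg.map_effect.log_odds(mapv)
        + cfg.temperature_effect.log_odds(temp)
        + cfg.gcs_effect * (gcs <= 14)
    )
    b0 = _calibrate_intercept(log_odds, cfg.target_mortality)
    died = rng.random(n) < expit(b0 + log_odds)

    records = [
        PatientRecord(
            patient_id=f"{label}-{i:05d}",
            age=int(age[i]),
            sex="male" if male[i] else "female",
            sbp=float(sbp[i]),
            dbp=float(dbp[i]),
            pulse=float(pulse[i]),
            resp_rate=float(resp[i]),
            temperature=float(round(temp[i], 1)),
            gcs=int(gcs[i]),
            wbc=float(wbc[i]),
            platelets=float(platelets[i]),
            suspected_infection=True,
            died_in_hospital=bool(died[i]),
        )
        for i in range(n)
    ]
    return Cohort(label=label, records=records)


def reconstruct_from_score_table(
    rows: Sequence[tuple[int, int, float]],
    label: str = "reconstructed",
) -> list[tuple[int, bool]]:
    """Per-patient (score, died) records from printed per-score rows.

    Each row ``(score, n_patients, mortality_pct)`` expands to
    ``n_patients`` records of which ``reconstruct_deaths`` determines the
    number that died.
    """
    out: list[tuple[int, bool]] = []
    for score_value, n_patients, pct in rows:
        deaths = reconstruct_deaths(n_patients, pct)
        out.extend((score_value, True) for _ in range(deaths))
        out.extend((score_value, False) for _ in range(n_patients - deaths))
    return out


def score_distribution_from_table(
    rows: Sequence[tuple[int, int, float]],
    label: str = "reconstructed",
):
    """ScoreDistribution with death counts reconstructed from printed rows."""
    from .scoring import ScoreDistribution

    return ScoreDistribution(
        label=label,
        rows=tuple((s, n, reconstruct_deaths(n, pct)) for s, n, pct in rows),
    )
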