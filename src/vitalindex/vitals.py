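"""Derived clinical quantities.

Mean arterial pressure, the four SIRS criteria, sepsis / severe-sepsis
classification and the three-level Glasgow-coma-score categorisation used
throughout the package.  Sepsis is defined clinically: suspected infection
plus at least two SIRS criteria; severe sepsis additionally requires one
organ dysfunction (GCS < 15, SBP < 90 mmHg, or platelets < 100 ×10³/cc).

White-cell counts are stored in thousands of cells per cc, so the SIRS
white-cell criterion compares against 12 and 4 (not 12 000 and 4 000).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .cohort import PatientRecord

__all__ = [
    "SepsisStatus",
    "mean_arterial_pressure",
    "sirs_criteria",
    "sirs_count",
    "classify_sepsis",
    "gcs_category",
    "GCS_CATEGORIES",
]

GCS_CATEGORIES = ("≤12", "13–14", "15")


@dataclass(frozen=True)
class SepsisStatus:
    """SIRS count, sepsis flags and the organ dysfunctions found."""

    sirs_count: int
    has_sepsis: bool
    has_severe_sepsis: bool
    organ_dysfunctions: frozenset[str] = dc_field(default_factory=frozenset)
    wbc_unavailable: bool = False

    def __post_init__(self) -> None:
        if self.has_severe_sepsis and not self.has_sepsis:
            raise ValueError("severe sepsis implies sepsis")
        if not 0 <= self.sirs_count <= 4:
            raise ValueError("sirs_count must be between 0 and 4")


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """Weighted average of systolic and diastolic pressure, (SBP + 2·DBP)/3.

    The result always lies between the diastolic and systolic values.
    """
    if dbp <= 0 or sbp <= 0:
        raise ValueError("pressures must be positive")
    if dbp > sbp:
        raise ValueError(f"dbp ({dbp}) exceeds sbp ({sbp})")
    return (sbp + 2.0 * dbp) / 3.0


def sirs_criteria(record: PatientRecord) -> dict[str, bool]:
    """Evaluate the four SIRS criteria on one record.

    Tachycardia: pulse ≥ 90/min.  Tachypnea: respiratory rate ≥ 20/min.
    Temperature derangement: ≥ 38 °C or ≤ 36 °C.  White-cell derangement:
    WBC ≥ 12 or < 4 (×10³/cc) or band forms > 10 %.  When both WBC and band
    forms are unrecorded the white-cell criterion counts as absent and the
    ``wbc_unavailable`` key flags it.
    """
    wbc_unavailable = record.wbc is None and record.band_forms_pct is None
    wbc_deranged = False
    if record.wbc is not None:
        wbc_deranged = record.wbc >= 12 or record.wbc < 4
    if record.band_forms_pct is not None:
        wbc_deranged = wbc_deranged or record.band_forms_pct > 10
    return {
        "tachycardia": record.pulse >= 90,
        "tachypnea": record.resp_rate >= 20,
        "temperature": record.temperature >= 38 or record.temperature <= 36,
        "white_cells": wbc_deranged,
        "wbc_unavailable": wbc_unavailable,
    }


def sirs_count(record: PatientRecord) -> int:
    """Number of SIRS criteria satisfied (0–4)."""
    crit = sirs_criteria(record)
    return sum(
        crit[k] for k in ("tachycardia", "tachypnea", "temperature", "white_cells")
    )


def classify_sepsis(record: PatientRecord) -> SepsisStatus:
    """Classify one admission as sepsis / severe sepsis.

    Sepsis requires suspected infection plus ≥ 2 SIRS criteria; severe
    sepsis additionally requires at least one organ dysfunction among
    low GCS (< 15), low SBP (< 90 mmHg) and low platelets (< 100 ×10³/cc).
    """
    crit = sirs_criteria(record)
    n = sum(
        crit[k] for k in ("tachycardia", "tachypnea", "temperature", "white_cells")
    )
    has_sepsis = record.suspected_infection and n >= 2

    dysfunctions = set()
    if record.gcs < 15:
        dysfunctions.add("low_gcs")
    if record.sbp < 90:
        dysfunctions.add("low_sbp")
    if record.platelets is not None and record.platelets < 100:
        dysfunctions.add("low_platelets")

    has_severe = has_sepsis and bool(dysfunctions)
    return SepsisStatus(
        sirs_count=n,
        has_sepsis=has_sepsis,
        has_severe_sepsis=has_severe,
        organ_dysfunctions=frozenset(dysfunctions if has_sepsis else dysfunctions),
        wbc_unavailable=crit["wbc_unavailable"],
    )


def gcs_category(gcs: int) -> str:
    """Three-level Glasgow-coma-score category: "≤12", "13–14" or "15"."""
    if not 3 <= gcs <= 15:
        raise ValueError(f"gcs must be in [3, 15], got {gcs}")
    if gcs <= 12:
        return "≤12"
    if gcs <= 14:
        return "13–14"
    return "15"
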