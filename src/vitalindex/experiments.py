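"""Self-validation experiments for the derivation pipeline.

Two seeded simulation experiments characterise the cutoff-derivation
procedure on cohorts from the synthetic generator:

* **planted-cutoff recovery** — cohorts carry known threshold effects; the
  pipeline should place an extracted cutoff within a small tolerance of
  every planted cutoff;
* **null safety** — cohorts whose outcome is independent of the vitals;
  the pipeline should produce no prognostic interval at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .derivation import CutoffDeriver
from .scoring import VARIABLE_RESOLUTION, IndexDefinition
from .synthetic import GeneratorConfig, generate_cohort

__all__ = [
    "extracted_cutoffs",
    "RecoveryResult",
    "recovery_experiment",
    "null_experiment",
]


def extracted_cutoffs(definition: IndexDefinition) -> dict[str, list[float]]:
    """Finite boundaries of the scored (1-point) bands, per variable."""
    out: dict[str, list[float]] = {}
    import math

    for comp in definition.components:
        edges: set[float] = set()
        for band in comp.bands:
            if band.points >= 1:
                if math.isfinite(band.low):
                    edges.add(band.low)
                if math.isfinite(band.high):
                    edges.add(band.high)
        out[comp.variable] = sorted(edges)
    return out


@dataclass
class RecoveryResult:
    """Per-cutoff hit counts over the simulated seeds."""

    n_seeds: int
    hits: dict[tuple[str, float], int]
    recovered_values: dict[tuple[str, float], list[float | None]]

    def rate(self, variable: str, cutoff: float) -> float:
        return self.hits[(variable, cutoff)] / self.n_seeds

    @property
    def min_rate(self) -> float:
        return min(h / self.n_seeds for h in self.hits.values())


def recovery_experiment(
    seeds: Sequence[int],
    config: GeneratorConfig | None = None,
    tolerance_units: float = 2.0,
    deriver_params: Mapping | None = None,
) -> RecoveryResult:
    """Derive cutoffs on generated cohorts and score planted-cutoff hits.

    A planted cutoff counts as recovered in one seed when some extracted
    boundary of the same vital lies within ``tolerance_units`` measurement
    resolutions of it.
    """
    base = config or GeneratorConfig()
    planted = base.planted_cutoffs
    hits = {(v, c): 0 for v, cuts in planted.items() for c in cuts}
    values: dict[tuple[float, float], list] = {k: [] for k in hits}
    for seed in seeds:
        cohort = generate_cohort(base.model_copy(update={"seed": int(seed)}))
        deriver = CutoffDeriver(**(dict(deriver_params) if deriver_params else {}))
        deriver.fit_cohort(cohort)
        found = extracted_cutoffs(deriver.index_definition_)
        for variable, cuts in planted.items():
            res = VARIABLE_RESOLUTION[variable]
            for cutoff in cuts:
                candidates = found.get(variable, [])
                near = [
                    b for b in candidates
                    if abs(b - cutoff) <= tolerance_units * res + 1e-9
                ]
                if near:
                    hits[(variable, cutoff)] += 1
                    values[(variable, cutoff)].append(
                        min(near, key=lambda b: abs(b - cutoff))
                    )
                else:
                    values[(variable, cutoff)].append(None)
    return RecoveryResult(
        n_seeds=len(seeds), hits=hits, recovered_values=values
    )


def null_experiment(
    seeds: Sequence[int],
    config: GeneratorConfig | None = None,
    deriver_params: Mapping | None = None,
) -> tuple[int, int]:
    """Run the pipeline on null-risk cohorts.

    Returns ``(n_clean, n_seeds)`` where a seed is clean when no vital
    yields a prognostic interval and no GCS cutoff is derived.
    """
    base = (config or GeneratorConfig()).null_risk()
    clean = 0
    for seed in seeds:
        cohort = generate_cohort(base.model_copy(update={"seed": int(seed)}))
        deriver = CutoffDeriver(**(dict(deriver_params) if deriver_params else {}))
        deriver.fit_cohort(cohort)
        no_intervals = all(
            cs.is_flat for cs in deriver.category_sets_.values()
        )
        if no_intervals and deriver.gcs_component_ is None:
            clean += 1
    return clean, len(seeds)
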