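# Methods

## The index and its comparator

The package centres on a binary-banded prognostic index for adults admitted
with sepsis.  Each admission vital contributes one point when abnormal:

| vital | abnormal range | points |
|---|---|---|
| respiratory rate | ≥ 30 cycles/min | 1 |
| pulse | ≥ 100 beats/min | 1 |
| mean arterial pressure | < 70 or ≥ 110 mmHg | 1 |
| axillary temperature | < 35.6 or ≥ 38.6 °C | 1 |
| Glasgow coma score | ≤ 14 | 1 |

MAP is always computed as (SBP + 2·DBP)/3 from the recorded pressures, never
accepted as an independent input, so a record cannot carry an inconsistent
pressure triple.  The maximum score is 5.

The MEWS comparator is implemented from its classic band enumeration
(maximum 14).  Two printed ambiguities required a decision: touching bands
("SBP 70 to 80", "80 to 100") are resolved half-open with the shared
boundary assigned to the higher-severity band (so SBP 80 scores 2 and
SBP 100 scores 1), and pulse < 40 — absent from the enumeration — scores 0
and raises a `RuntimeWarning` rather than being silently imputed from other
MEWS variants.

## Validation statistics

Per-score mortality tables are dichotomised at score ≥ 3 (≥ 5 for MEWS) and
summarised with the Woolf (log-odds-ratio Wald) estimator:

    OR = ad/bc,  SE = √(1/a + 1/b + 1/c + 1/d),
    95 % CI = exp(ln OR ± 1.96·SE),  p = 2·Φ(−|ln OR|/SE).

This estimator reproduces all four published confidence bounds and both
p-values at display precision (OR and CI to one decimal, two significant
figures below 1; p to three decimals), and it coincides with the maximum
likelihood coefficient of a single-binary-predictor logistic regression —
a property the tests verify against statsmodels on randomized tables.
Zero cells raise by default; the Haldane–Anscombe +0.5 correction is
available explicitly (`haldane=True`) but never applied silently, because a
silent correction would distort reproduction of published values.

Death counts are reconstructed from printed per-score percentages by
rounding half away from zero; that convention reproduces both cohorts'
totals exactly (development 39/167 → 23 %, validation 45/150 → 30 %).
Multiple imputation used in the original development analysis is out of
scope; all analyses here are complete-case.

## Cutoff derivation

For each continuous vital the pipeline fits a univariable logistic
regression of in-hospital death on a restricted cubic spline basis
(truncated-power natural-spline construction; k knots, default 4, at the
5/35/65/95th percentiles of the observed values; the basis is linear beyond
the boundary knots).  The fitted mortality curve is evaluated on a grid at
measurement resolution (1 beat or cycle/min, 0.1 °C, ⅓ mmHg for MAP), and
values are segmented into *reference* categories — model mortality at or
below the cohort mean p̄ plus a tolerance band of +2 percentage points
("below or about average") — and *prognostic* categories above it.  The
+2 pp band is configurable; it reflects that observed category mortalities
a point or two above the mean are still read as unremarkable.

Three safeguards surround the bare curve-crossing rule, each the package's
own design decision:

1. **Association screen.**  Segmentation only proceeds when the spline
   model beats the intercept-only model in a likelihood-ratio test at
   α = 0.005 (k−1 df).  Without the screen, spline tail noise at n = 5000
   produces spurious prognostic intervals on roughly half of outcome-
   independent cohorts; with it, a four-vital derivation on null data flags
   anything with probability ≈ 2 %.  The Glasgow coma score, handled
   categorically (levels ≤ 12, 13–14, 15, collapsed to ≤ 14 versus 15), gets
   the analogous two-proportion chi-square screen at the same level.
2. **Changepoint refinement.**  Each curve crossing of p̄ + 2 pp is replaced
   by the two-level binomial maximum-likelihood changepoint within ±15
   resolution units (records within twice that window).  A few-knot spline
   smears a sharp mortality step over the inter-knot distance; when most of
   the data mass lies beyond the step (pulse: ~64 % of admissions are above
   100 beats/min), the smeared crossing is displaced upward by 5–10
   beats/min.  The local changepoint is insensitive to that mass asymmetry.
3. **Category confirmation.**  Categories between refined boundaries are
   re-labelled by their *observed* mortality against the same threshold
   (curve first, observed category mortality second); categories with fewer
   than 20 admissions are absorbed into the neighbour with the closer
   mortality before labelling; adjacent same-label categories merge.  A
   vital whose final partition is a single reference category contributes
   no component to the derived index.

Cutoffs are the boundaries between reference and prognostic categories,
rounded to the vital's clinical resolution.  Fitting requires at least 50
complete records and both outcome classes; separation or non-convergence
raises with advice to reduce the knot count.

## The synthetic generator

The generator emulates a sepsis admission cohort for pipeline testing.
Marginals (medians matching the original development cohort, spread
consistent with its inter-quartile ranges):

* pulse ~ log-normal(median 108, σ 0.2132); respiratory rate ~ log-normal
  (28, 0.2777); WBC ~ log-normal(4.7, 0.616); platelets ~ log-normal
  (160, 0.557); age ~ log-normal(38, 0.50);
* SBP/DBP ~ correlated log-normal pair (medians 100/60, σ 0.28/0.32,
  ρ = 0.6) with DBP clamped below SBP; MAP follows as (SBP + 2·DBP)/3 with
  median ≈ 73.  The pressure spreads sit at the upper end of the published
  IQR envelope so that the MAP ≥ 110 cutoff lies inside the spline's knot
  span rather than in an unmodellable extreme tail;
* temperature ~ normal(37.0, 1.33) at 0.1 °C resolution; GCS categorical
  (80 % at 15, 14 % at 13–14, 6 % at ≤ 12, matching the published ~21 %
  altered mental state); 53 % male; suspected infection always true (the
  cohorts enrolled sepsis admissions).

Death follows a logistic model whose log-odds rise by a **threshold
effect** when a vital crosses its planted cutoff — respiratory rate ≥ 30:
+1.2 (plus 0.04 per cycle beyond); pulse ≥ 100: +1.0 (plus 0.01 per beat,
capped at 30 beats); MAP outside 70–110: +1.6; temperature outside
35.6–38.6 °C: +1.2 (plus 0.15 per squared °C beyond); GCS ≤ 14: +0.9 — and
whose intercept is calibrated by bisection so expected mortality matches
the target (default 23 %).  `GeneratorConfig.null_risk()` zeroes every
effect for null-safety experiments.

Two deliberate choices here:

* **Step effects, not smooth hinges.**  The derivation's estimand is the
  point where a vital's marginal mortality curve crosses the cohort
  average.  For any smooth monotone risk contribution f, that crossing sits
  where f(c) ≈ E[f(X)], which can never lie below the vital's mean — so a
  smooth hinge placed at pulse 100 (36th percentile of the pulse marginal)
  yields a true crossing near 112–120, and "recovery of the planted cutoff"
  would be impossible by construction.  A step effect pins the crossing of
  both the mean and the mean + 2 pp band exactly at the threshold,
  whatever the mass split around it, making the planted cutoff a
  well-defined estimand.
* **Amplitudes above the published contrasts.**  The study's own category
  contrasts (e.g. pulse ≥ 100: 26 % vs 20 % mortality) carry too little
  Fisher information at n = 5000 to localise a boundary to ±2 resolution
  units by *any* method (≈ 11 pp marginal jumps at ~15 records/mmHg give
  changepoint errors of several units).  The planted amplitudes
  (1.0–1.6 log-odds) are chosen once so each cutoff is identifiable at the
  default cohort size; the recovery experiment therefore tests the
  pipeline's correctness, not the original study's power.

What the generator does **not** emulate: the true joint dependence between
vitals (only SBP–DBP correlation is modelled; other vitals are drawn
independently), missing data, repeated measurements, and site or treatment
structure.  Passing recovery tests therefore show the pipeline finds
cutoffs planted under independence and complete data; they do not show the
original cohort's effect sizes were recoverable, nor how the pipeline
behaves under correlated confounding between vitals.

## Self-validation experiments and sizes

* **Planted-cutoff recovery** — 20 seeded cohorts of n = 5000; a planted
  cutoff counts as recovered when some extracted boundary of that vital
  lies within ±2 resolution units (±2 mmHg, ±2 beats or cycles/min,
  ±0.2 °C).  Expected performance ≥ 90 % per cutoff (typically 19–20/20;
  occasional misses concentrate on MAP ≥ 110, the thinnest data region).
* **Null safety** — 20 seeded null-risk cohorts of n = 5000; a seed is
  clean when every vital yields a single reference category and no GCS
  cutoff is derived.  Expected ≥ 90 % (typically 19–20/20, the screen's
  design rate being ≈ 98 %).
* **Oracle agreement** — 200 random non-degenerate 2×2 tables; Woolf log-OR
  versus the statsmodels logistic MLE agrees within 1e−6 (observed ~1e−10).
* **Generator calibration** — n = 10 000: marginal medians within 5 % of
  the published medians (observed worst ≈ 1–2 %), realized mortality within
  2 pp of target (observed ≲ 0.5 pp).

These sizes keep the full test suite and the acceptance script each within
a few tens of seconds on one CPU while leaving the binomial pass
probabilities of the seeded experiments above 95 %.

## Numerical notes and degenerate inputs

* Spline fits use statsmodels GLM/Binomial (IRLS maximum likelihood);
  predicted probabilities are clipped to [0, 1] only against floating-point
  spill.
* The changepoint scan needs ≥ 5 records on each side of a candidate and
  falls back to the unrefined crossing otherwise.
* Ties at band boundaries are exact numeric comparisons at the printed
  thresholds (≥, <) with temperature at 0.1 °C granularity.
* A curve entirely below p̄ + 2 pp, a screened-out vital, or a prognostic
  candidate with < 20 admissions all degrade gracefully to a single
  reference category (the vital is omitted from the derived index).
* The generator's intercept bisection is deterministic and converges to
  1e−6 in expected mortality; reported cohorts then vary binomially around
  the target.
* Empty cohorts, single-class outcomes, duplicate patient identifiers and
  out-of-range vitals are rejected with specific exceptions rather than
  propagating NaNs.

## Known limitations

* The derivation assumes univariable relationships (as in the source
  procedure); confounding between vitals can displace marginal crossings.
* In thin tails the confirmed prognostic region occasionally splits (for
  instance pulse `[100, 159) → 1` with a reference tail) when the observed
  tail mortality happens to dip; the cutoff adjacent to the data mass is
  the reliable one.
* Printed-table reconstruction inverts rounded percentages; it is exact for
  these two cohorts but not guaranteed for arbitrary published tables.
* MEWS odds ratios from the original study cannot be recomputed because no
  per-score MEWS distribution was published; the reproduction command
  covers the proposed index and overall mortality.
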