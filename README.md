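# vitalindex

Admission vital signs are often the only monitoring signal available when
triaging acutely ill patients in resource-limited hospitals.  `vitalindex`
implements a *reduced-segmentation* prognostic index for adults admitted
with sepsis — one point per abnormal admission vital, rather than the
multi-band point scales of scores like MEWS — together with the statistical
machinery used to derive and validate such an index:

* **Scoring** — the proposed five-point index (respiratory rate ≥ 30
  cycles/min, pulse ≥ 100 beats/min, mean arterial pressure ≥ 110 or
  < 70 mmHg, axillary temperature ≥ 38.6 or < 35.6 °C, Glasgow coma score
  ≤ 14: one point each) and the Modified Early Warning Score comparator
  (maximum 14).
* **Derivation** — univariable logistic regressions of in-hospital death on
  restricted cubic splines of each vital (k knots, default 4, at the
  5/35/65/95th percentiles), segmentation of each vital's range into
  reference categories (model mortality at or below the cohort average
  p̄, within a +2 pp band) and prognostic categories (above it), and
  extraction of binary cutoffs from the category boundaries.
* **Validation statistics** — per-score mortality tables, dichotomisation at
  score ≥ 3, and Woolf (log-OR Wald) odds ratios:
  `OR = ad/bc`, `CI = exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`.
* **Clinical definitions** — MAP = (SBP + 2·DBP)/3, the four SIRS criteria,
  and sepsis / severe-sepsis classification.
* **Synthetic cohorts** — a seedable generator whose marginals match the
  original development cohort's medians and whose risk model carries
  *planted* threshold effects at the published cutoffs, so the whole
  derivation pipeline can be tested by cutoff recovery.

## Worked example

Reproduce the published validation statistics of the index from the
per-score mortality tables of the two original cohorts (development
n = 167, validation n = 150):

```bash
$ vitalindex reproduce
development: OR 3.4 (1.6 to 7.3), p = 0.001, overall mortality 23%
validation: OR 2.3 (1.1 to 4.7), p = 0.031, overall mortality 30%
```

Patients scoring ≥ 3 were 3.4-fold (development) and 2.3-fold (validation)
as likely to die in hospital as patients scoring 0–2; overall in-hospital
mortality was 23 % and 30 %.  The command exits non-zero if any recomputed
value deviates from the published ones.

Derive cutoffs end-to-end on a synthetic cohort with planted thresholds:

```bash
$ vitalindex simulate --n 5000 --seed 7 --out cohort.csv
simulated 5000 records (seed 7), realized mortality 0.233 -> cohort.csv
$ vitalindex derive cohort.csv --out index.json
map: prognostic interval(s) [(27.3, 70.0), (110.0, 194.7)]
temperature: prognostic interval(s) [(32.6, 35.5), (38.5, 41.8)]
pulse: prognostic interval(s) [(100.0, 257.0)]
resp_rate: prognostic interval(s) [(30.0, 80.0)]
index definition -> index.json
```

The derived cutoffs (MAP < 70 / ≥ 110, temperature < 35.5 / ≥ 38.5, pulse
≥ 100, respiratory rate ≥ 30) recover the planted values to within one
resolution unit.  The same pipeline is available as a scikit-learn style
estimator:

```python
from vitalindex import CutoffDeriver, IndexScorer, proposed_index_definition

deriver = CutoffDeriver().fit(X, y)   # X: vitals frame, y: died in hospital
deriver.index_definition_             # derived cutoffs as scoring bands
scores = IndexScorer(proposed_index_definition()).fit_transform(X)
```

Other subcommands: `validate` (CSV schema and clinical-range checks),
`classify` (MAP, SIRS count, sepsis flags), `score`, `validate-index`
(score distribution, 2×2 table, Woolf OR), `fixture` (per-patient records
reconstructed from the published score tables).

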