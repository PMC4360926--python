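import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2

from vitalindex.cohort import Cohort, PatientRecord
from vitalindex.derivation import (
    CutoffDeriver,
    FitError,
    default_knots,
    derive_categories,
    fit_risk_curve,
    rcs_basis,
)
from vitalindex.experiments import extracted_cutoffs
from vitalindex.synthetic import GeneratorConfig, generate_cohort


def cohort_from_arrays(x, y, variable="pulse", label="sim"):
    """Single-vital cohort; the other vitals are held at reference values."""
    records = []
    for i, (xi, yi) in enumerate(zip(x, y)):
        fields = dict(
            patient_id=f"{label}-{i}", sbp=110.0, dbp=70.0, pulse=80.0,
            resp_rate=16.0, temperature=36.8, gcs=15,
            suspected_infection=True, died_in_hospital=bool(yi),
        )
        fields[variable] = float(xi)
        records.append(PatientRecord(**fields))
    return Cohort(label=label, records=records)


class TestRcsBasis:
    def test_k_knots_give_k_minus_one_columns(self):
        x = np.linspace(0, 10, 50)
        for k in (3, 4, 5):
            knots = np.linspace(1, 9, k)
            assert rcs_basis(x, knots).shape == (50, k - 1)

    def test_first_column_is_raw_values(self):
        x = np.linspace(0, 10, 20)
        basis = rcs_basis(x, np.array([2.0, 5.0, 8.0]))
        assert np.allclose(basis[:, 0], x)

    def test_nonlinear_terms_vanish_at_and_below_first_knot(self):
        knots = np.array([3.0, 5.0, 7.0, 9.0])
        basis = rcs_basis(np.array([1.0, 2.5, 3.0]), knots)
        assert np.allclose(basis[:, 1:], 0.0)

    def test_linear_tails_beyond_boundary_knots(self):
        knots = np.array([3.0, 5.0, 7.0, 9.0])
        h = 1e-3
        for x0 in (9.5, 11.0, 30.0):
            pts = rcs_basis(np.array([x0 - h, x0, x0 + h]), knots)
            second = (pts[0] - 2 * pts[1] + pts[2]) / h**2
            assert np.all(np.abs(second) < 1e-6)

    def test_too_few_or_duplicate_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.arange(5.0), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            rcs_basis(np.arange(5.0), np.array([1.0, 1.0, 2.0]))

    def test_default_knots_are_percentiles(self):
        x = np.arange(1000.0)
        assert np.allclose(default_knots(x, 4),
                           np.percentile(x, [5, 35, 65, 95]))


class TestFitRiskCurve:
    def test_null_risk_curve_is_flat_at_event_rate(self):
        rng = np.random.default_rng(42)
        x = np.round(np.exp(rng.normal(np.log(100), 0.2, 2000)))
        y = rng.random(2000) < 0.25
        curve = fit_risk_curve(cohort_from_arrays(x, y), "pulse")
        lo, hi = np.percentile(x, [10, 90])
        mid = (curve.grid >= lo) & (curve.grid <= hi)
        assert np.all(np.abs(curve.p_death[mid] - 0.25) < 0.05)

    def test_linear_logit_data_agrees_with_plain_logistic_between_knots(self):
        rng = np.random.default_rng(7)
        n = 20000
        x = rng.normal(50, 10, n)
        y = rng.random(n) < expit(-3.0 + 0.04 * x)
        curve = fit_risk_curve(cohort_from_arrays(np.round(x), y, "pulse"), "pulse")
        design = sm.add_constant(np.round(x))
        linear = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        inner = (curve.grid >= curve.knots[0]) & (curve.grid <= curve.knots[-1])
        plain = linear.predict(sm.add_constant(curve.grid[inner]))
        assert np.max(np.abs(curve.p_death[inner] - plain)) < 0.02

    def test_small_cohorts_are_refused(self, record_factory):
        records = [record_factory(patient_id=f"p{i}", died_in_hospital=(i % 2 == 0))
                   for i in range(10)]
        with pytest.raises(FitError, match="at least 50"):
            fit_risk_curve(Cohort("tiny", records), "pulse")

    def test_single_class_outcome_is_refused(self, record_factory):
        records = [record_factory(patient_id=f"p{i}") for i in range(60)]
        with pytest.raises(FitError, match="single class"):
            fit_risk_curve(Cohort("alive", records), "pulse")

    def test_probabilities_within_unit_interval(self, medium_synthetic_cohort):
        curve = fit_risk_curve(medium_synthetic_cohort, "map")
        assert np.all((curve.p_death >= 0) & (curve.p_death <= 1))
        assert np.all(np.diff(curve.grid) > 0)

    def test_no_spurious_nonlinearity_in_linear_limit(self):
        """Spline vs plain-logistic deviance gap stays below the chi-square
        95th percentile on k-2 df in at least 90 % of linear-logit sims."""
        rng = np.random.default_rng(0)
        crit = chi2.ppf(0.95, df=2)  # k=4 knots -> 2 extra params
        passes = 0
        n_sims = 20
        for _ in range(n_sims):
            n = 2000
            x = rng.normal(50, 10, n)
            y = rng.random(n) < expit(-3.0 + 0.04 * x)
            knots = default_knots(x, 4)
            spline = sm.GLM(
                y, sm.add_constant(rcs_basis(x, knots)),
                family=sm.families.Binomial(),
            ).fit()
            linear = sm.GLM(
                y, sm.add_constant(x), family=sm.families.Binomial()
            ).fit()
            if 2 * (spline.llf - linear.llf) < crit:
                passes += 1
        assert passes >= int(0.9 * n_sims)


class TestDeriveCategories:
    def test_flat_null_curve_gives_single_reference_category(self):
        rng = np.random.default_rng(5)
        x = np.round(np.exp(rng.normal(np.log(100), 0.2, 3000)))
        y = rng.random(3000) < 0.25
        cohort = cohort_from_arrays(x, y)
        cats = derive_categories(fit_risk_curve(cohort, "pulse"), cohort)
        assert len(cats.categories) == 1
        assert cats.is_flat and cats.categories[0].is_reference

    def test_u_shaped_map_risk_gives_three_categories(self):
        cohort = generate_cohort(GeneratorConfig(n=5000, seed=23))
        cats = derive_categories(fit_risk_curve(cohort, "map"), cohort)
        labels = [c.is_reference for c in cats.categories]
        assert labels == [False, True, False]

    def test_hinge_shaped_resp_rate_boundary_near_planted_cutoff(self):
        cohort = generate_cohort(GeneratorConfig(n=5000, seed=23))
        cats = derive_categories(fit_risk_curve(cohort, "resp_rate"), cohort)
        (lo, _hi), = cats.prognostic_intervals
        assert abs(lo - 30.0) <= 2.0

    def test_category_intervals_partition_observed_range(self,
                                                         medium_synthetic_cohort):
        cohort = medium_synthetic_cohort
        cats = derive_categories(fit_risk_curve(cohort, "temperature"), cohort)
        assert sum(c.n for c in cats.categories) == len(cohort)
        for left, right in zip(cats.categories[:-1], cats.categories[1:]):
            assert left.high == right.low


class TestCutoffDeriver:
    def test_full_pipeline_recovers_planted_cutoffs_one_seed(self):
        cohort = generate_cohort(GeneratorConfig(n=5000, seed=23))
        deriver = CutoffDeriver().fit_cohort(cohort)
        found = extracted_cutoffs(deriver.index_definition_)
        expected = {
            "resp_rate": [(30.0, 2.0)],
            "pulse": [(100.0, 2.0)],
            "map": [(70.0, 2.0), (110.0, 2.0)],
            "temperature": [(35.6, 0.2), (38.6, 0.2)],
        }
        for variable, cuts in expected.items():
            for planted, tol in cuts:
                assert any(abs(b - planted) <= tol for b in found[variable]), (
                    variable, planted, found[variable],
                )
        assert deriver.gcs_component_ is not None

    def test_sklearn_interface(self):
        cohort = generate_cohort(GeneratorConfig(n=1500, seed=4))
        frame = cohort.to_frame()
        X = frame[["sbp", "dbp", "pulse", "resp_rate", "temperature", "gcs"]]
        y = frame["died_in_hospital"].to_numpy()
        deriver = CutoffDeriver(include_gcs=False)
        assert deriver.get_params()["k_knots"] == 4
        deriver.set_params(k_knots=4)
        scores = deriver.fit(X, y).transform(X.head(10))
        assert len(scores) == 10
        assert hasattr(deriver, "index_definition_")

    def test_unfitted_transform_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            CutoffDeriver().transform(pd.DataFrame())
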