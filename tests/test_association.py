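import math

import numpy as np
import pytest
import statsmodels.api as sm

from vitalindex.association import (
    TwoByTwo,
    category_mortality,
    dichotomize,
    format_or_ci,
    format_p,
    odds_ratio_woolf,
    overall_mortality,
    reconstruct_deaths,
)
from vitalindex.derivation import variable_values
from vitalindex.synthetic import (
    DEVELOPMENT_SCORE_TABLE,
    VALIDATION_SCORE_TABLE,
    score_distribution_from_table,
)


class TestReconstructDeaths:
    @pytest.mark.parametrize(
        "n,pct,expected",
        [(57, 25, 14), (2, 100, 2), (0, 50, 0), (28, 11, 3), (32, 6.3, 2),
         (36, 36, 13), (12, 42, 5), (3, 33, 1), (26, 27, 7), (38, 16, 6),
         (59, 34, 20), (18, 33, 6), (6, 83, 5), (10, 25, 3)],  # 2.5 rounds away
    )
    def test_round_half_away_from_zero(self, n, pct, expected):
        assert reconstruct_deaths(n, pct) == expected

    def test_invalid_percentages_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_deaths(10, 120)

    def test_published_totals_reproduced(self):
        dev = score_distribution_from_table(DEVELOPMENT_SCORE_TABLE)
        val = score_distribution_from_table(VALIDATION_SCORE_TABLE)
        assert (dev.n_patients, dev.n_deaths) == (167, 39)
        assert (val.n_patients, val.n_deaths) == (150, 45)


class TestDichotomize:
    def test_development_two_by_two(self):
        dist = score_distribution_from_table(DEVELOPMENT_SCORE_TABLE)
        t = dichotomize(dist, 3)
        assert (t.a, t.b, t.c, t.d) == (20, 30, 19, 98)

    def test_validation_two_by_two(self):
        dist = score_distribution_from_table(VALIDATION_SCORE_TABLE)
        t = dichotomize(dist, 3)
        assert (t.a, t.b, t.c, t.d) == (31, 52, 14, 53)

    def test_threshold_below_minimum_warns_of_empty_arm(self):
        dist = score_distribution_from_table(DEVELOPMENT_SCORE_TABLE)
        with pytest.warns(RuntimeWarning, match="empty arm"):
            with pytest.raises(ValueError):
                dichotomize(dist, 0)  # everyone exposed -> invalid table


class TestWoolf:
    def test_development_result_matches_published_display(self):
        result = odds_ratio_woolf(TwoByTwo(20, 30, 19, 98))
        assert result.display() == "3.4 (1.6 to 7.3)"
        assert format_p(result.p_value) == "0.001"

    def test_validation_result_matches_published_display(self):
        result = odds_ratio_woolf(TwoByTwo(31, 52, 14, 53))
        assert result.display() == "2.3 (1.1 to 4.7)"
        assert format_p(result.p_value) == "0.031"

    @pytest.mark.parametrize("k", [1, 5, 40])
    def test_uniform_table_is_null_and_log_symmetric(self, k):
        result = odds_ratio_woolf(TwoByTwo(k, k, k, k))
        assert result.odds_ratio == pytest.approx(1.0)
        assert result.ci_low * result.ci_high == pytest.approx(1.0)
        assert result.p_value == pytest.approx(1.0)

    def test_zero_cell_raises_unless_haldane(self):
        table = TwoByTwo(0, 10, 5, 10)
        with pytest.raises(ValueError, match="zero cell"):
            odds_ratio_woolf(table)
        corrected = odds_ratio_woolf(table, haldane=True)
        assert corrected.method == "haldane_corrected"
        assert corrected.odds_ratio > 0

    def test_exposure_swap_inverts_or_and_ci(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 200, 4)
            fwd = odds_ratio_woolf(TwoByTwo(int(a), int(b), int(c), int(d)))
            rev = odds_ratio_woolf(TwoByTwo(int(c), int(d), int(a), int(b)))
            assert fwd.odds_ratio == pytest.approx(1 / rev.odds_ratio)
            assert fwd.ci_low == pytest.approx(1 / rev.ci_high)
            assert fwd.p_value == pytest.approx(rev.p_value)

    def test_matches_logistic_regression_oracle(self):
        """Woolf log-OR equals the MLE coefficient of a one-predictor
        logistic regression, within 1e-6, on randomized tables."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            a, b, c, d = (int(v) for v in rng.integers(1, 300, 4))
            result = odds_ratio_woolf(TwoByTwo(a, b, c, d))
            exposure = np.r_[np.ones(a + b), np.zeros(c + d)]
            outcome = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
            fit = sm.GLM(
                outcome, sm.add_constant(exposure), family=sm.families.Binomial()
            ).fit()
            assert abs(math.log(result.odds_ratio) - fit.params[1]) < 1e-6

    def test_p_value_ci_duality(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(1, 120, 4))
            r = odds_ratio_woolf(TwoByTwo(a, b, c, d))
            excludes_one = r.ci_low > 1 or r.ci_high < 1
            assert (r.p_value < 0.05) == excludes_one


class TestFormatting:
    @pytest.mark.parametrize("value,text", [(3.4386, "3.4"), (2.2569, "2.3"),
                                            (0.7415, "0.74"), (1.04, "1.0"),
                                            (7.275, "7.3")])
    def test_display_rounding(self, value, text):
        assert format_or_ci(value) == text


class TestCohortLevelSummaries:
    def test_overall_mortality_published_values(self):
        dev = score_distribution_from_table(DEVELOPMENT_SCORE_TABLE)
        val = score_distribution_from_table(VALIDATION_SCORE_TABLE)
        assert overall_mortality(dev)[1] == 23
        assert overall_mortality(val)[1] == 30

    def test_all_survivor_distribution_is_zero(self):
        dist = score_distribution_from_table([(0, 12, 0.0)])
        assert overall_mortality(dist) == (0.0, 0)

    def test_category_mortality_partition_conservation(self,
                                                       medium_synthetic_cohort):
        cohort = medium_synthetic_cohort
        values = variable_values(cohort, "map")
        rows = category_mortality(
            cohort, values, [(-np.inf, 70.0), (70.0, 110.0), (110.0, np.inf)]
        )
        assert sum(r["n"] for r in rows) == len(cohort)

    def test_map_reference_band_has_lowest_mortality(self,
                                                     medium_synthetic_cohort):
        cohort = medium_synthetic_cohort
        values = variable_values(cohort, "map")
        rows = category_mortality(
            cohort, values, [(-np.inf, 70.0), (70.0, 110.0), (110.0, np.inf)]
        )
        middle = rows[1]["mortality_pct"]
        assert middle < rows[0]["mortality_pct"]
        assert middle < rows[2]["mortality_pct"]

    def test_non_partition_is_rejected(self, medium_synthetic_cohort):
        cohort = medium_synthetic_cohort
        values = variable_values(cohort, "map")
        with pytest.raises(ValueError, match="partition"):
            category_mortality(cohort, values, [(-np.inf, 70.0), (80.0, np.inf)])
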