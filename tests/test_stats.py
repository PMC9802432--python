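"""Chi-square / ANOVA / t-test behavior, cross-checked against independent routes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cdst_hru.stats import (
    GroupSummary,
    anova_oneway,
    anova_oneway_from_summary,
    chi_square_test,
    compare_strata,
    t_test_two_sample,
)


class TestChiSquare:
    def test_published_sex_table_reproduces_printed_p(self):
        result = chi_square_test([[532, 403], [295, 215]])
        assert round(result.p_value, 3) == 0.729
        assert result.df == 1

    def test_identical_row_proportions_give_zero_statistic(self):
        result = chi_square_test([[20, 80], [10, 40]])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_statistic_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            table = rng.integers(1, 60, size=(3, 2)).astype(float)
            observed = chi_square_test(table)
            # independent route: direct sum((O-E)^2 / E)
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            expected = row @ col / table.sum()
            statistic = ((table - expected) ** 2 / expected).sum()
            assert observed.statistic == pytest.approx(statistic, rel=1e-12)
            assert observed.p_value == pytest.approx(sps.chi2.sf(statistic, 2), rel=1e-12)

    def test_invariant_under_row_and_column_permutation(self):
        table = np.array([[41, 138], [52, 100], [19, 8]])
        base = chi_square_test(table).statistic
        assert chi_square_test(table[::-1]).statistic == pytest.approx(base)
        assert chi_square_test(table[:, ::-1]).statistic == pytest.approx(base)

    def test_zero_margin_names_degenerate_axis(self):
        with pytest.raises(ValueError, match="column 1"):
            chi_square_test([[5, 0], [7, 0]])

    def test_small_expected_counts_warn_in_result(self):
        result = chi_square_test([[2, 3], [4, 1]])
        assert result.warning and "expected count" in result.warning


class TestAnova:
    def test_published_age_summaries_reproduce_printed_p(self):
        groups = [GroupSummary(179, 46.3, 16.8), GroupSummary(152, 45.2, 14.9), GroupSummary(27, 36.9, 13.6)]
        result = anova_oneway_from_summary(groups)
        assert round(result.p_value, 3) == 0.016

    def test_identical_groups_give_f_zero(self):
        result = anova_oneway_from_summary([(50, 10.0, 2.0), (60, 10.0, 2.0)])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_summary_route_agrees_with_observation_level_scipy(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(loc, 1.5, size=n) for loc, n in ((0.0, 25), (0.4, 30), (0.8, 20))]
        ours = anova_oneway(*groups)
        reference = sps.f_oneway(*groups)
        assert ours.statistic == pytest.approx(reference.statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(reference.pvalue, rel=1e-9)

    def test_two_group_f_equals_squared_pooled_t(self):
        a, b = GroupSummary(40, 5.0, 1.2), GroupSummary(35, 5.6, 1.4)
        f = anova_oneway_from_summary([a, b])
        t = t_test_two_sample(a, b)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            anova_oneway_from_summary([(1, 0.0, 0.0), (10, 1.0, 1.0)])


class TestTTest:
    def test_identical_summaries_give_t_zero(self):
        result = t_test_two_sample((30, 4.0, 1.0), (45, 4.0, 1.0))
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_published_disease_duration_is_highly_significant(self):
        result = t_test_two_sample((935, 3.2, 3.0), (510, 5.0, 3.7))
        assert result.p_value < 0.001

    def test_raw_values_and_their_summaries_agree(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        from_raw = t_test_two_sample(a, b)
        from_summary = t_test_two_sample(
            (len(a), a.mean(), a.std(ddof=1)), (len(b), b.mean(), b.std(ddof=1))
        )
        assert from_raw.statistic == pytest.approx(from_summary.statistic, rel=1e-9)

    def test_three_groups_rejected(self):
        with pytest.raises(ValueError, match="exactly 2"):
            t_test_two_sample((10, 1.0, 1.0), (10, 1.0, 1.0), (10, 1.0, 1.0))


class TestCompareStrata:
    def test_single_stratum_returns_empty_with_warning(self):
        data = pd.DataFrame({"stratum": ["high"] * 10, "had_surgery": [True] * 3 + [False] * 7})
        with pytest.warns(UserWarning, match="fewer than 2"):
            result = compare_strata(data, binary_outcomes=["had_surgery"])
        assert len(result) == 0

    def test_table_layout_matches_publication_style(self):
        rng = np.random.default_rng(5)
        n = 120
        data = pd.DataFrame(
            {
                "stratum": ["high"] * n + ["low"] * n,
                "had_surgery": np.concatenate([rng.random(n) < 0.1, rng.random(n) < 0.4]),
                "total": np.concatenate([rng.lognormal(9, 1, n), rng.lognormal(9.7, 1, n)]),
            }
        )
        result = compare_strata(data, binary_outcomes=["had_surgery"], continuous_outcomes=["total"])
        assert list(result["variable"]) == ["had_surgery", "total"]
        assert {"high_summary", "low_summary"} <= set(result.columns)
        assert (result["p_value"] < 0.05).all()  # planted 4x rate and ~2x cost differences

    def test_planted_rate_difference_is_detected(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(100):
            high = rng.random(500) < 0.10
            low = rng.random(500) < 0.20
            data = pd.DataFrame(
                {"stratum": ["high"] * 500 + ["low"] * 500, "event": np.concatenate([high, low])}
            )
            p = compare_strata(data, binary_outcomes=["event"])["p_value"].iloc[0]
            rejections += p < 0.05
        assert rejections > 90  # power >> alpha for a 2x rate difference at n=500/stratum
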