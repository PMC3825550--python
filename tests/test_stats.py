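"""Dose-response statistics: binning, normalisation, tests, adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from zfcardio import (
    AnalysisError,
    ConfigError,
    bin_by_fi,
    bonferroni_pairwise,
    chi_square_2x2,
    normalize_expression,
    spearman_corr,
    t_test_two_sided,
)


class TestBinByFI:
    def test_half_open_boundary_convention(self):
        df = pd.DataFrame({"FI": [1.99, 2.0, 3.99, 4.0, 7.99, 8.0, 50.0]})
        out = bin_by_fi(df)
        labels = out["fi_bin"].astype(str).tolist()
        assert labels[0] == "FI < 2"
        assert labels[1] == labels[2] == "2 <= FI < 4"
        assert labels[3] == labels[4] == "4 <= FI < 8"
        assert labels[5] == labels[6] == "FI >= 8"

    def test_empty_records_give_empty_groups(self):
        out = bin_by_fi(pd.DataFrame({"FI": []}))
        assert len(out) == 0
        assert out["fi_bin"].cat.categories.size == 4

    def test_unsorted_edges_config_error(self):
        with pytest.raises(ConfigError):
            bin_by_fi(pd.DataFrame({"FI": [1.0]}), edges=(4, 2, 8))


class TestNormalizeExpression:
    def test_sample_scaled_by_control_mean(self):
        df = pd.DataFrame(
            {"FI": [0.5, 0.8, 5.0], "expression_ratio": [1.0, 1.0, 0.5]}
        )
        out = normalize_expression(df)
        assert out.loc[2, "relative_expression"] == pytest.approx(0.5)

    def test_single_control_of_two(self):
        df = pd.DataFrame({"FI": [0.5, 5.0], "expression_ratio": [2.0, 1.0]})
        out = normalize_expression(df)
        assert out.loc[1, "relative_expression"] == pytest.approx(0.5)

    def test_all_control_input_has_unit_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"FI": rng.uniform(0, 1, 20), "expression_ratio": rng.uniform(0.5, 2, 20)}
        )
        out = normalize_expression(df)
        assert out["relative_expression"].mean() == pytest.approx(1.0)

    def test_empty_control_subset_errors(self):
        df = pd.DataFrame({"FI": [5.0, 6.0], "expression_ratio": [1.0, 1.0]})
        with pytest.raises(AnalysisError):
            normalize_expression(df)


class TestSpearman:
    def test_perfect_monotone_correlations(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        rho_up, _ = spearman_corr(x, x**3)
        rho_dn, _ = spearman_corr(x, -np.sqrt(x))
        assert rho_up == pytest.approx(1.0)
        assert rho_dn == pytest.approx(-1.0)

    def test_exact_p_for_perfect_small_sample(self):
        # n = 4 distinct: only the 2 perfectly monotone permutations reach |rho| = 1
        rho, p = spearman_corr([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_constant_vector_errors(self):
        with pytest.raises(AnalysisError):
            spearman_corr([1, 2, 3, 4], [5, 5, 5, 5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=-100, max_value=100),
            min_size=5, max_size=12, unique=True,
        )
    )
    def test_invariant_under_monotone_transform(self, xs):
        # integer inputs keep exp(x/50) strictly monotone in floating point
        x = np.asarray(xs, dtype=float)
        rng = np.random.default_rng(0)
        y = rng.permutation(x)
        try:
            rho1, p1 = spearman_corr(x, y)
        except AnalysisError:
            return
        rho2, p2 = spearman_corr(np.exp(x / 50.0), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)


class TestTTest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = t_test_two_sided(a, a)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_well_separated_groups(self):
        a = np.array([0.0, 0.001, -0.001, 0.0005])
        b = np.array([1.0, 1.001, 0.999, 1.0005])
        _, p = t_test_two_sided(a, b)
        assert p < 1e-4

    def test_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t1, p1 = t_test_two_sided(a, b)
        t2, p2 = t_test_two_sided(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_conventions(self):
        assert t_test_two_sided([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
        t, p = t_test_two_sided([0.0, 0.0], [1.0, 1.0])
        assert np.isinf(t) and p == 0.0

    def test_welch_variant_matches_reference(self):
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 3, 14)
        t, p = t_test_two_sided(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestBonferroni:
    def test_three_groups_three_comparisons(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(0, 1, 10) for g in "abc"}
        out = bonferroni_pairwise(groups)
        assert len(out) == 3
        for c in out:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 3))
            assert c.p_adjusted >= c.p_raw

    def test_identical_groups_adjusted_to_one(self):
        a = np.array([1.0, 2.0, 3.0])
        out = bonferroni_pairwise({"x": a, "y": a.copy(), "z": a.copy()})
        assert all(c.p_adjusted == 1.0 for c in out)

    def test_two_sd_shifted_groups_all_significant(self):
        rng = np.random.default_rng(3)
        groups = {
            "lo": rng.normal(0.0, 1.0, 50),
            "mid": rng.normal(2.0, 1.0, 50),
            "hi": rng.normal(4.0, 1.0, 50),
        }
        out = bonferroni_pairwise(groups)
        assert all(c.p_adjusted < 0.01 for c in out)

    def test_single_comparison_unchanged(self):
        rng = np.random.default_rng(4)
        out = bonferroni_pairwise({"a": rng.normal(0, 1, 8), "b": rng.normal(0, 1, 8)})
        assert len(out) == 1
        assert out[0].p_adjusted == pytest.approx(out[0].p_raw)

    def test_undersized_group_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        groups = {"a": rng.normal(0, 1, 8), "b": rng.normal(0, 1, 8),
                  "tiny": np.array([1.0])}
        with pytest.warns(UserWarning, match="n < 2"):
            out = bonferroni_pairwise(groups)
        assert len(out) == 1

    def test_dataframe_input(self):
        df = pd.DataFrame(
            {"group": ["a"] * 5 + ["b"] * 5, "EF": np.r_[np.ones(5), 2 * np.ones(5)]}
        )
        df["EF"] += np.random.default_rng(6).normal(0, 0.01, 10)
        out = bonferroni_pairwise(df, metric="EF")
        assert out[0].p_raw < 1e-6


class TestChiSquare:
    def test_independent_table_is_zero(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 10*625/ (5*5*5*5) ... = 10
        chi2, p = chi_square_2x2([[5, 0], [0, 5]])
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(1.565e-3, rel=1e-3)

    def test_rescue_contingency_table_significant(self):
        # morphant alone: 2 unaffected / 13 congested; + rescue mRNA: 16 / 4
        chi2, p = chi_square_2x2([[2, 13], [16, 4]])
        assert chi2 == pytest.approx(35 * (2 * 4 - 13 * 16) ** 2 / (15 * 20 * 18 * 17))
        assert p < 0.05

    def test_invariant_under_transpose_and_swaps(self):
        t = np.array([[3, 7], [9, 2]])
        base = chi_square_2x2(t)
        assert chi_square_2x2(t.T) == pytest.approx(base)
        assert chi_square_2x2(t[::-1]) == pytest.approx(base)
        assert chi_square_2x2(t[:, ::-1]) == pytest.approx(base)

    def test_yates_correction_reduces_statistic(self):
        plain, _ = chi_square_2x2([[2, 13], [16, 4]])
        corrected, _ = chi_square_2x2([[2, 13], [16, 4]], yates=True)
        assert corrected < plain

    def test_zero_margin_errors(self):
        with pytest.raises(AnalysisError):
            chi_square_2x2([[0, 0], [5, 5]])
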