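import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qeeg
from qeeg.errors import DegenerateDataError, ValidationError
from qeeg.stats import (
    analyze_cohort,
    bh_fdr,
    chi_square,
    delta_nihss,
    independent_t,
    paired_t,
    pearson_corr,
)

from _oracles import bh_oracle


class TestPairedT:
    def test_hand_computed_example(self):
        # differences (1,2,3,4): mean 2.5, sd 1.2910 -> t = 3.873, df 3
        x1 = np.array([10.0, 10.0, 10.0, 10.0])
        x0 = x1 + np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x0, x1)
        assert res.statistic == pytest.approx(3.8730, abs=1e-4)
        assert res.df == 3
        assert res.p_raw == pytest.approx(0.0305, abs=2e-3)

    def test_degenerate_differences(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            paired_t(x, x)
        with pytest.raises(DegenerateDataError):
            paired_t(x + 1.0, x)  # constant shift, zero-variance diffs

    def test_matches_scipy_oracle(self, rng):
        from scipy.stats import ttest_rel
        a, b = rng.standard_normal((2, 30))
        res = paired_t(a, b)
        ref = ttest_rel(a, b)
        assert abs(res.statistic - ref.statistic) < 1e-8
        assert abs(res.p_raw - ref.pvalue) < 1e-6


class TestIndependentT:
    def test_closed_form_example(self):
        res = independent_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == 4

    def test_identical_groups_give_t_zero(self, rng):
        g = rng.standard_normal(20)
        res = independent_t(g, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(15) + 0.5
        r1, r2 = independent_t(a, b), independent_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_welch_variant(self, rng):
        from scipy.stats import ttest_ind
        a = rng.standard_normal(10)
        b = rng.standard_normal(25) * 4
        res = independent_t(a, b, pooled=False)
        ref = ttest_ind(a, b, equal_var=False)
        assert abs(res.statistic - ref.statistic) < 1e-10
        assert res.df == pytest.approx(ref.df)

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            independent_t([1.0, 1.0], [1.0, 1.0])


class TestChiSquare:
    def test_null_table(self):
        res = chi_square([[20, 20], [20, 20]])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_hand_computed(self):
        # sum (O-E)^2/E with all E = 20 -> 4 * 100/20 = 20
        res = chi_square([[30, 10], [10, 30]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_transpose_invariance_2x2(self):
        t = np.array([[12, 23], [31, 14]])
        assert chi_square(t).statistic == pytest.approx(
            chi_square(t.T).statistic)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi_square([[0, 0], [10, 20]])

    def test_yates_reduces_statistic(self):
        t = [[30, 10], [10, 30]]
        assert chi_square(t, yates=True).statistic < chi_square(t).statistic


class TestPearson:
    def test_hand_computed(self):
        res = pearson_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)
        assert res.n == 4

    def test_exact_lines(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_corr(x, -x).r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_from_t_transform(self, rng):
        from scipy.stats import t as tdist
        x, y = rng.standard_normal((2, 25))
        res = pearson_corr(x, y)
        tt = res.r * np.sqrt((res.n - 2) / (1 - res.r ** 2))
        p = 2 * tdist.sf(abs(tt), res.n - 2)
        assert res.p == pytest.approx(p, abs=1e-10)


class TestBHFDR:
    def test_examples(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_families_corrected_separately(self):
        p = np.array([0.01, 0.04, 0.01, 0.04])
        fams = np.array(["a", "a", "b", "b"])
        q = bh_fdr(p, fams)
        np.testing.assert_allclose(q[:2], bh_fdr(p[:2]))
        np.testing.assert_allclose(q[2:], bh_fdr(p[2:]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=10))
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=8))
    def test_monotone_in_p_within_family(self, p):
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


class TestDeltaNIHSS:
    @pytest.mark.parametrize("t0,t1,expect", [(13, 6, 7), (12, 12, 0),
                                              (5, 8, -3)])
    def test_difference(self, t0, t1, expect):
        rec = qeeg.SubjectRecord("s", "control", "left", 60, "F", t0, t1)
        assert delta_nihss(rec) == expect


class TestAnalyzeCohort:
    def test_full_battery_structure(self, small_cohort, small_features):
        hemi = qeeg.hemisphere_features(small_features, small_cohort.subjects)
        report = analyze_cohort(hemi, small_cohort.subjects)
        df = report.frame()
        assert set(df["family"]) == {"eeg_within_experimental",
                                     "eeg_within_control", "eeg_between_T1",
                                     "clinical", "baseline"}
        assert np.all((df["p_raw"] >= 0) & (df["p_raw"] <= 1))
        assert np.all((df["q_fdr"] >= 0) & (df["q_fdr"] <= 1))
        # q >= p within each family (step-up can only inflate)
        assert np.all(df["q_fdr"] >= df["p_raw"] - 1e-12)
        corr = report.correlation_frame()
        assert "alpha_beta_ratio" in set(corr["feature"])
        assert np.all(corr["r"].abs() <= 1.0)
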