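"""Group tests, correlation inference, variance components, subgroup rules."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.stats.power as smp
from hypothesis import given, settings
from hypothesis import strategies as st

from myoglyco import cohort as coh
from myoglyco import synthetic as syn


def two_group_frame(mhn, mhs, name="v"):
    return pd.DataFrame({
        "dx": ["MHN"] * len(mhn) + ["MHS"] * len(mhs),
        name: np.concatenate([mhn, mhs]),
    })


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        vals = np.linspace(1, 5, 12)
        c = coh.compare_groups(two_group_frame(vals, vals), "v")
        assert c.p > 0.9

    def test_power_matches_t_test_oracle(self):
        """Rejection rate at a 1-SD shift matches closed-form t-test power."""
        oracle = smp.TTestIndPower().power(effect_size=1.0, nobs1=13, ratio=12 / 13,
                                           alpha=0.05)
        rng = np.random.default_rng(7)
        n_rep, rejections = 800, 0
        for _ in range(n_rep):
            df = two_group_frame(rng.normal(0, 1, 13), rng.normal(1, 1, 12))
            rejections += coh.compare_groups(df, "v").p <= 0.05
        rate = rejections / n_rep
        se = np.sqrt(oracle * (1 - oracle) / n_rep)
        assert abs(rate - oracle) < 4 * se + 0.02  # procedure may fall back to u test

    def test_heavy_tails_select_mann_whitney(self):
        rng = np.random.default_rng(3)
        picks = 0
        n_rep = 200
        for _ in range(n_rep):
            df = two_group_frame(rng.standard_cauchy(13), rng.standard_cauchy(12))
            picks += coh.compare_groups(df, "v").test_used == "mann_whitney"
        assert picks / n_rep > 0.9

    def test_normal_equal_variance_selects_t(self):
        rng = np.random.default_rng(5)
        picks = sum(
            coh.compare_groups(
                two_group_frame(rng.normal(0, 1, 13), rng.normal(0, 1, 12)), "v"
            ).test_used == "t"
            for _ in range(100)
        )
        assert picks > 80  # two gates at alpha 0.05 each

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(42)
        n_rep, rejections = 2000, 0
        for _ in range(n_rep):
            df = two_group_frame(rng.normal(0, 1, 13), rng.normal(0, 1, 12))
            rejections += coh.compare_groups(df, "v").p <= 0.05
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            coh.compare_groups(two_group_frame([1.0, 2.0], [1.0, 2.0, 3.0]), "v")


class TestCorrelation:
    def test_published_worked_examples(self):
        _, p_t, _, _ = coh.correlation_pvalues(0.58, 25)
        assert round(p_t, 3) == 0.002
        _, p_t2, _, _ = coh.correlation_pvalues(0.21, 560)
        assert p_t2 < 0.001

    def test_zero_correlation_is_null(self):
        t, p_t, v, p_v = coh.correlation_pvalues(0.0, 30)
        assert t == 0.0 and p_t == 1.0 and v == 0.0 and p_v == 1.0

    def test_matches_scipy_pearsonr(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = coh.pearson_with_p(x, y)
        ref = pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic)
        assert res.p_t == pytest.approx(ref.pvalue, rel=1e-9)

    def test_t_and_fisher_p_agree_in_the_usable_range(self):
        """The two null approximations agree closely wherever p is not
        deep in the tails (far-tail probability ratios diverge for any
        pair of approximations even as both vanish)."""
        for r in (0.1, 0.3, 0.5, 0.7, 0.89):
            for n in (20, 50, 200, 500):
                _, p_t, _, p_v = coh.correlation_pvalues(r, n)
                if p_t >= 1e-3:
                    assert max(p_t, p_v) / min(p_t, p_v) < 1.5

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2, 3, 4, np.nan, 6])
        y = np.array([1.1, 2.2, 2.9, 4.3, 5.0, np.nan])
        assert coh.pearson_with_p(x, y).n == 4

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            coh.pearson_with_p(np.ones(10), np.arange(10.0))


class TestPercentDifference:
    @pytest.mark.parametrize(
        "mhn, mhs, expected",
        [
            (3.63, 7.05, 94),    # GDE means (microsomes)
            (1.32, 2.22, 68),    # phospho-enzyme means (whole muscle)
            (0.36, 0.51, 42),    # phosphorylation-ratio medians (whole muscle)
            (0.76, 1.37, 80),    # synthase phosphorylation-ratio medians
            (3.33, 4.28, 29),    # all-forms enzyme medians (whole muscle)
            (3.81, 6.50, 71),    # phospho-enzyme means (microsomes)
        ],
    )
    def test_group_statistic_worked_examples(self, mhn, mhs, expected):
        assert round(coh.percent_difference(mhn, mhs)) == expected

    def test_equal_statistics_zero(self):
        assert coh.percent_difference(2.0, 2.0) == 0.0

    @settings(deadline=None, max_examples=30)
    @given(
        ref=st.floats(min_value=0.01, max_value=1e3),
        val=st.floats(min_value=0.0, max_value=1e3),
        k=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, ref, val, k):
        assert coh.percent_difference(k * ref, k * val) == pytest.approx(
            coh.percent_difference(ref, val), rel=1e-9, abs=1e-9
        )

    def test_table_interface(self):
        df = two_group_frame([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert coh.percent_difference(df, variable="v", statistic="median") == pytest.approx(100.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            coh.percent_difference(0.0, 5.0)


class TestMultivariateRegression:
    def test_single_predictor_reduces_to_pearson(self):
        df = syn.simulate_cohort(syn.CohortParams(), seed=3)
        fit = coh.multivariate_regression(df, "PhK_mc", ["GP_mc"])
        r = coh.pearson_with_p(df["GP_mc"], df["PhK_mc"])
        assert fit.multivariate_r == pytest.approx(abs(r.r), rel=1e-9)

    def test_noiseless_coefficients_exact(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=60), rng.normal(size=60)
        df = pd.DataFrame({"y": 2 * x1 - x2, "x1": x1, "x2": x2})
        fit = coh.multivariate_regression(df, "y", ["x1", "x2"])
        assert fit.coefficients.loc["x1", "coef"] == pytest.approx(2.0, abs=1e-6)
        assert fit.coefficients.loc["x2", "coef"] == pytest.approx(-1.0, abs=1e-6)

    def test_imposed_signs_recovered_on_simulated_cohorts(self):
        good = 0
        n_rep = 100
        for s in range(n_rep):
            df = syn.simulate_cohort(syn.CohortParams(n_mhn=25, n_mhs=25), seed=5000 + s)
            fit = coh.multivariate_regression(df, "PhK_mc", ["GPa_wm", "glycogen_mc"])
            good += (
                fit.coefficients.loc["GPa_wm", "coef"] > 0
                and fit.coefficients.loc["glycogen_mc", "coef"] < 0
            )
        assert good / n_rep >= 0.95

    def test_collinear_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        df = pd.DataFrame({"y": x + rng.normal(size=40), "a": x, "b": 2 * x})
        with pytest.warns(UserWarning, match="collinear"):
            fit = coh.multivariate_regression(df, "y", ["a", "b"])
        assert fit.dropped == ["b"]

    def test_direct_mode_returns_per_response_fits(self):
        df = syn.simulate_cohort(syn.CohortParams(), seed=9)
        fits = coh.multivariate_regression(df, "PhK_mc", ["GP_mc", "GDE_mc"], mode="direct")
        assert isinstance(fits, list) and len(fits) == 2
        assert fits[0].predictors == ["PhK_mc"]


class TestVarianceDecomposition:
    def test_printed_component_arithmetic(self):
        vd = coh.variance_decomposition_from_components(0.0303, 0.0026)
        assert vd.sd_single == pytest.approx(0.166, abs=5e-4)
        assert vd.threshold_2sd_percent == pytest.approx(33.0, abs=0.5)
        assert vd.probable_error_of_mean_percent(13) == pytest.approx(9.0, abs=0.5)

    def test_all_identical_replicates_zero(self):
        df = syn.simulate_replicate_table(
            syn.ReplicateParams(lane_cv=0.0, tech_cv=0.0), seed=0
        )
        vd = coh.variance_decomposition(df)
        assert vd.total_frac_var == pytest.approx(0.0, abs=1e-12)
        assert vd.technical_frac_var == pytest.approx(0.0, abs=1e-12)
        assert vd.sd_single == pytest.approx(0.0, abs=1e-6)

    def test_single_rep_everywhere_rejected(self):
        df = syn.simulate_replicate_table(
            syn.ReplicateParams(tech_reps_per_lane=1), seed=0
        )
        with pytest.raises(ValueError, match="technical"):
            coh.variance_decomposition(df)

    def test_estimator_bias_small_at_large_n(self):
        params = syn.ReplicateParams(n_patients=400, lane_cv=0.165, tech_cv=0.051)
        vd = coh.variance_decomposition(syn.simulate_replicate_table(params, seed=2))
        truth = 0.165**2 + 0.051**2
        assert abs(vd.total_frac_var - truth) / truth < 0.05


class TestSubgroupSelection:
    def test_dominant_patient_ranks_first(self):
        df = syn.simulate_cohort(syn.CohortParams(), seed=0)
        top = df["id"].iloc[-1]
        df.loc[df["id"] == top, ["PhK_mc", "GP_mc"]] = [99.0, 99.0]
        mc, _ = coh.select_mc_mn(df, k=6)
        assert mc[0] == top

    def test_k_equal_group_size_selects_all(self):
        df = syn.simulate_cohort(syn.CohortParams(), seed=1)
        n_mhs = int((df["dx"] == "MHS").sum())
        mc, _ = coh.select_mc_mn(df, k=n_mhs)
        assert sorted(mc) == sorted(df.loc[df["dx"] == "MHS", "id"])

    def test_low_subgroup_enriched_for_negative_diagnosis(self):
        """Bottom-rank subgroup is almost always pure MHN, far above the ~1% null."""
        all_mhn = 0
        n_rep = 100
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(n_rep):
                df = syn.simulate_cohort(syn.CohortParams(), seed=1000 + s)
                _, mn = coh.select_mc_mn(df, k=6)
                all_mhn += (df.set_index("id").loc[mn, "dx"] == "MHN").all()
        assert all_mhn / n_rep > 0.5

    def test_k_too_large_rejected(self):
        df = syn.simulate_cohort(syn.CohortParams(), seed=2)
        with pytest.raises(ValueError):
            coh.select_mc_mn(df, k=13)


class TestFbsExcess:
    def test_discussion_worked_example(self):
        assert coh.fbs_excess_estimate(2.5, 0.15) == 0.38

    def test_from_group_medians(self):
        assert coh.fbs_excess_estimate(2.5, 0.51 - 0.36) == 0.38

    def test_zero_slope(self):
        assert coh.fbs_excess_estimate(0.0, 0.15) == 0.0
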