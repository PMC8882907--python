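import numpy as np
import pytest
from scipy import stats as sps

from pediconn.stats import (
    clinical_correlation,
    fdr_within_hemisphere,
    fit_ols,
    group_difference_test,
    interaction_test,
    pergroup_age_correlation,
    rank_sum_test,
    sample_with_moments,
)


class TestFitOls:
    def test_hand_simple_regression(self):
        """y=[1,2,2,3] on x=[1,2,3,4]: slope 0.6, t=4.2426, df 2."""
        X = np.column_stack([np.ones(4), [1, 2, 3, 4]])
        res = fit_ols([1, 2, 2, 3], X, ["intercept", "x"])
        slope = res[1]
        assert slope.coef == pytest.approx(0.6)
        assert slope.t == pytest.approx(np.sqrt(18), rel=1e-4)  # 4.2426
        assert slope.df == 2

    def test_exact_fit_flags_infinite_t(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        res = fit_ols(2 * np.arange(5.0) + 1, X, ["intercept", "x"])
        assert np.isinf(res[1].t)
        assert res[1].p == 0.0

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="x2"):
            fit_ols(np.random.default_rng(0).normal(size=5), X, ["intercept", "x1", "x2"])

    def test_matches_statsmodels_on_random_problems(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        for _ in range(20):
            n, p = int(rng.integers(8, 30)), int(rng.integers(2, 4))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            ours = fit_ols(y, X, [f"b{i}" for i in range(p)])
            ref = sm.OLS(y, X).fit()
            for i, r in enumerate(ours):
                assert r.coef == pytest.approx(ref.params[i], rel=1e-9)
                assert r.t == pytest.approx(ref.tvalues[i], rel=1e-9)
                assert r.p == pytest.approx(ref.pvalues[i], rel=1e-9, abs=1e-12)
                assert r.df == int(ref.df_resid)

    def test_t_and_p_are_consistent(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        res = fit_ols(rng.normal(size=12), X, ["c", "x"])[1]
        assert res.p == pytest.approx(2 * sps.t.sf(abs(res.t), res.df))


class TestGroupDifference:
    def test_constant_age_reduces_to_pooled_t(self):
        res = group_difference_test(
            [1, 2, 3, 3, 4, 5],
            ["TD"] * 3 + ["ASD"] * 3,
            [4.0] * 6,
        )
        assert res.t == pytest.approx(-2.449, abs=2e-3)
        assert res.df == 4
        assert res.coef == pytest.approx(-2.0)  # TD - ASD

    def test_summary_statistics_reconstruction_reproduces_reported_t(self):
        """Groups rebuilt from printed means/SDs (TD 39.85+/-8.02 n=21,
        ASD 47.51+/-6.68 n=30) give the pooled t of -3.710; the same
        comparison with an independent age covariate stays within 0.5%."""
        td = sample_with_moments(39.85, 8.02, 21, seed=1)
        asd = sample_with_moments(47.51, 6.68, 30, seed=2)
        y = np.concatenate([td, asd])
        labels = ["TD"] * 21 + ["ASD"] * 30
        res = group_difference_test(y, labels, np.full(51, 4.0))
        assert res.t == pytest.approx(-3.710, abs=5e-4)
        # an age covariate orthogonal to group and outcome leaves the
        # coefficient untouched; only the residual df changes (49 -> 48)
        rng = np.random.default_rng(3)
        raw = rng.uniform(2.33, 5.96, 51)
        g = np.array([1.0] * 21 + [0.0] * 30)
        Z = np.column_stack([np.ones(51), g, y])
        ages = raw - Z @ np.linalg.lstsq(Z, raw, rcond=None)[0] + 4.0
        res_age = group_difference_test(y, labels, ages)
        assert res_age.df == 48
        assert res_age.t == pytest.approx(-3.710, rel=0.02)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(77)
        labels = ["TD"] * 21 + ["ASD"] * 30
        ages = np.concatenate([rng.uniform(1.99, 5.96, 21), rng.uniform(2.33, 7.0, 30)])
        rej = sum(
            group_difference_test(rng.normal(size=51), labels, ages).p < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rej / 1000 <= 0.07

    def test_sign_convention_td_minus_asd(self):
        rng = np.random.default_rng(8)
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])  # ASD higher
        labels = ["TD"] * 20 + ["ASD"] * 20
        res = group_difference_test(y, labels, rng.uniform(2, 7, 40))
        assert res.t < 0


class TestInteraction:
    def test_no_interaction_when_slopes_equal(self):
        ages = np.array([2.0, 3, 4, 5, 2, 3, 4, 5])
        y = 1.5 * ages + np.array([0, 0, 0, 0, 2, 2, 2, 2])  # shifted, same slope
        res = interaction_test(y, ["TD"] * 4 + ["ASD"] * 4, ages)
        assert res.interaction.coef == pytest.approx(0.0, abs=1e-10)
        assert res.slope_td == pytest.approx(1.5)
        assert res.slope_asd == pytest.approx(1.5)

    def test_planted_slope_gap_recovered(self):
        rng = np.random.default_rng(4)
        ages = np.concatenate([rng.uniform(2, 6, 40), rng.uniform(2, 7, 40)])
        labels = ["TD"] * 40 + ["ASD"] * 40
        slopes = np.where(np.asarray(labels) == "TD", 2.0, 0.8)
        y = slopes * ages + rng.normal(0, 0.3, 80)
        res = interaction_test(y, labels, ages)
        assert res.interaction.p < 1e-6
        assert res.slope_td - res.slope_asd == pytest.approx(1.2, abs=0.15)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(9)
        ages = rng.uniform(2, 7, 30)
        labels = np.where(rng.random(30) < 0.5, "TD", "ASD")
        y = rng.normal(size=30) + (labels == "TD") * ages * 0.5
        a = interaction_test(y, labels, ages)
        swapped = np.where(labels == "TD", "ASD", "TD")
        b = interaction_test(y, swapped, ages)
        assert a.interaction.coef == pytest.approx(-b.interaction.coef)
        assert abs(a.interaction.t) == pytest.approx(abs(b.interaction.t))

    def test_type_i_error_calibrated(self):
        """Under a no-interaction null the 5% test rejects ~5%."""
        rng = np.random.default_rng(2024)
        labels = ["TD"] * 21 + ["ASD"] * 30
        ages = np.concatenate([rng.uniform(1.99, 5.96, 21), rng.uniform(2.33, 7.0, 30)])
        rej = sum(
            interaction_test(rng.normal(size=51) + 0.3 * ages, labels, ages).interaction.p < 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rej / 2000 <= 0.07


class TestCorrelations:
    def test_perfect_and_hand_pearson(self):
        ages = np.array([1.0, 2, 3, 1, 2, 3])
        vals = np.array([1.0, 2, 3, 1, 3, 2])
        res = pergroup_age_correlation(vals, ages, ["TD"] * 3 + ["ASD"] * 3)
        assert res["TD"].r == pytest.approx(1.0)
        assert res["ASD"].r == pytest.approx(0.5)
        assert res["ASD"].n == 3

    def test_partial_correlation_perfect_linear(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(2, 7, 20)
        metric = rng.normal(size=20)
        res = clinical_correlation(metric, 3 * metric + 1, age)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_partial_equals_pearson_when_age_orthogonal(self):
        rng = np.random.default_rng(6)
        n = 40
        metric = rng.normal(size=n)
        score = 0.6 * metric + rng.normal(size=n) * 0.5
        # residualize both on a random age so age carries no shared signal
        age = rng.uniform(2, 7, n)
        X = np.column_stack([np.ones(n), age])
        metric_o = metric - X @ np.linalg.lstsq(X, metric, rcond=None)[0]
        score_o = score - X @ np.linalg.lstsq(X, score, rcond=None)[0]
        res = clinical_correlation(metric_o, score_o, age)
        assert res.r == pytest.approx(sps.pearsonr(metric_o, score_o)[0], abs=1e-9)

    def test_matches_pingouin_partial_correlation(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(13)
        n = 30
        age = rng.uniform(2, 7, n)
        metric = 0.5 * age + rng.normal(size=n)
        score = 0.4 * metric + 0.3 * age + rng.normal(size=n)
        ours = clinical_correlation(metric, score, age)
        ref = pg.partial_corr(
            data=pd.DataFrame({"m": metric, "s": score, "a": age}), x="m", y="s", covar="a"
        )
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


class TestFdrWithinHemisphere:
    def test_bh_step_up_all_rejected(self):
        rej, adj = fdr_within_hemisphere(
            [0.001, 0.01, 0.02, 0.04], ["L"] * 4, q=0.05
        )
        assert rej.all()

    def test_bh_step_up_only_smallest(self):
        rej, _ = fdr_within_hemisphere([0.01, 0.04, 0.04, 0.9], ["L"] * 4, q=0.05)
        assert rej.tolist() == [True, False, False, False]

    def test_all_ones_rejects_none(self):
        rej, _ = fdr_within_hemisphere([1.0] * 6, ["L", "R"] * 3, q=0.05)
        assert not rej.any()

    def test_hemispheres_are_independent_families(self):
        # 0.04 alone in R survives BH (k=1 of 1); among L's it would not
        p = [0.04, 0.026, 0.04, 0.9]
        hemi = ["R", "L", "L", "L"]
        rej, _ = fdr_within_hemisphere(p, hemi, q=0.05)
        assert bool(rej[0]) is True
        assert not rej[2]

    def test_never_rejects_p_above_q_and_monotone_in_q(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        hemi = np.array(["L", "R"] * 20)
        prev = -1
        for q in (0.01, 0.05, 0.1, 0.3):
            rej, _ = fdr_within_hemisphere(p, hemi, q=q)
            assert not np.any(rej & (p > q))
            assert rej.sum() >= prev
            prev = rej.sum()

    def test_nan_passthrough(self):
        rej, adj = fdr_within_hemisphere([0.01, np.nan, 0.02], ["L", "L", "L"], q=0.05)
        assert not rej[1] and np.isnan(adj[1])
        assert rej[0] and rej[2]


class TestRankSum:
    def test_exact_small_sample(self):
        """[1,2] vs [3,4]: 6 equally likely rank assignments, the
        observed split is the most extreme on both sides -> p = 1/3."""
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_close_to_normal_approximation_at_n10(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(size=10), rng.normal(0.5, 1, size=10)
        exact = rank_sum_test(a, b)
        approx = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
        assert exact == pytest.approx(approx, abs=0.02)
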