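"""Compound-symmetry GLS, ANOVA/Tukey-Kramer, rank tests, threshold regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cochleametrics.stats import (
    GlsSpec,
    RegressionSpec,
    anova_tukey,
    fit_gls_cs,
    fit_threshold_regression,
    kruskal_wallis,
    rank_tests,
    ranksum_test,
)
from cochleametrics.synthgen import BrightnessTableConfig, synth_brightness_table


def hand_gls(X, y, V):
    """Textbook GLS for a known covariance (the closed-form oracle)."""
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


class TestGls:
    def test_matches_hand_computation_at_fixed_rho(self):
        # balanced 2-cluster toy, 8 observations, rho fixed: closed-form GLS
        rho, sd = 0.4, 2.0
        table = pd.DataFrame({
            "animal": ["a"] * 4 + ["b"] * 4,
            "dose": [0.0] * 4 + [1.0] * 4,
            "site": ["s1", "s2", "s3", "s4"] * 2,
            "brightness": [10.0, 12.0, 9.0, 11.0, 7.0, 8.5, 6.0, 9.5],
        })
        res = fit_gls_cs(table, GlsSpec(fixed_effects=("dose",)), fix_rho=rho)
        X = np.column_stack([np.ones(8), table["dose"]])
        R = np.kron(np.eye(2), (1 - rho) * np.eye(4) + rho * np.ones((4, 4)))
        expected = hand_gls(X, table["brightness"].to_numpy(), R)
        np.testing.assert_allclose(res.params.to_numpy(), expected, rtol=1e-10)

    def test_rho_zero_reduces_to_ols(self):
        tab = synth_brightness_table(BrightnessTableConfig(
            n_animals_per_group=10, intra_animal_correlation=0.0, seed=3))
        res = fit_gls_cs(tab, fix_rho=0.0)
        import statsmodels.formula.api as smf

        ols = smf.ols("brightness ~ dose + C(site)", tab).fit()
        assert res.params["dose"] == pytest.approx(ols.params["dose"], rel=1e-9)
        assert res.bse["dose"] == pytest.approx(ols.bse["dose"], rel=1e-9)

    def test_matches_mixedlm_oracle(self):
        # random-intercept ML fit is the same model for rho >= 0
        import statsmodels.formula.api as smf

        tab = synth_brightness_table(BrightnessTableConfig(seed=42))
        res = fit_gls_cs(tab, reml=False)
        ml = smf.mixedlm("brightness ~ dose + C(site)", tab, groups=tab["animal"]).fit(reml=False)
        assert res.params["dose"] == pytest.approx(ml.params["dose"], rel=1e-6)
        assert res.loglik == pytest.approx(ml.llf, abs=1e-6)
        rho_ml = float(ml.cov_re.iloc[0, 0] / (ml.cov_re.iloc[0, 0] + ml.scale))
        assert res.rho == pytest.approx(rho_ml, abs=1e-5)

    def test_slope_recovery_with_ci_coverage(self):
        covered, ests = 0, []
        for s in range(50):
            tab = synth_brightness_table(BrightnessTableConfig(seed=300 + s))
            res = fit_gls_cs(tab)
            lo, hi = res.conf_int.loc["dose"]
            covered += lo <= -61.0 <= hi
            ests.append(res.params["dose"])
        assert covered / 50 >= 0.9
        assert np.mean(ests) == pytest.approx(-61.0, abs=3.0)

    def test_rank_deficiency_and_singletons_rejected(self):
        tab = pd.DataFrame({
            "animal": ["a", "b", "c", "d"],
            "dose": [0.0, 0.0, 1.0, 1.0],
            "site": ["s"] * 4,
            "brightness": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(ValueError, match="singleton"):
            fit_gls_cs(tab, GlsSpec(fixed_effects=("dose",)))
        tab2 = synth_brightness_table(BrightnessTableConfig(n_animals_per_group=5, seed=1))
        tab2["dupe"] = tab2["dose"]
        with pytest.raises(ValueError, match="rank"):
            fit_gls_cs(tab2, GlsSpec(fixed_effects=("dose", "dupe", "site")))

    def test_group_relabeling_invariance(self):
        tab = synth_brightness_table(BrightnessTableConfig(n_animals_per_group=8, seed=5))
        res1 = fit_gls_cs(tab)
        tab2 = tab.copy()
        tab2["animal"] = "zz_" + tab2["animal"]
        res2 = fit_gls_cs(tab2)
        assert res1.params["dose"] == pytest.approx(res2.params["dose"], rel=1e-12)


class TestAnovaTukey:
    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.7, 1, 25)
        res = anova_tukey(np.concatenate([a, b]), ["a"] * 20 + ["b"] * 25)
        t, _ = sps.ttest_ind(a, b)
        assert res["F"] == pytest.approx(t**2, rel=1e-9)

    def test_width_difference_scenario(self, rng):
        # three groups at the study's sizes; control vs high differ by 29 um
        ctrl = rng.normal(230.0, 12.0, 30)
        low = rng.normal(218.0, 12.0, 19)
        high = rng.normal(201.0, 12.0, 22)
        values = np.concatenate([ctrl, low, high])
        groups = ["control"] * 30 + ["low"] * 19 + ["high"] * 22
        res = anova_tukey(values, groups)
        assert res["p"] < 0.001
        pair = res["pairwise"]
        row = pair[(pair.group1 == "control") & (pair.group2 == "high")].iloc[0]
        assert row["lower"] <= -29.0 + 12 and row["upper"] >= -29.0 - 12
        assert row["reject"]

    def test_identical_groups_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            anova_tukey([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])

    def test_null_p_uniformish(self, rng):
        ps = []
        for _ in range(200):
            v = rng.normal(0, 1, 30)
            ps.append(anova_tukey(v, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)["p"])
        # Kolmogorov-Smirnov against uniform
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestRankTests:
    def test_report_fields_and_shift_detection(self, rng):
        # study-shaped comparison: n = 26 vs 32 with a real shift
        x = rng.normal(1.0, 1.0, 26)
        y = rng.normal(0.0, 1.0, 32)
        res = rank_tests(x, y)
        assert set(res) >= {"ranksum", "Z", "p"}
        assert res["p"] < 0.05
        # W is the sum of x's midranks
        assert res["ranksum"] == pytest.approx(
            sps.rankdata(np.concatenate([x, y]))[:26].sum())

    def test_identical_samples_z_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ranksum_test(x, x)
        assert res["Z"] == 0.0 and res["p"] == 1.0

    def test_matches_scipy_when_no_ties(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.3, 1, 18)
        res = ranksum_test(x, y)
        z_scipy = sps.ranksums(x, y).statistic
        # continuity correction shrinks |Z| slightly
        assert abs(res["Z"]) <= abs(z_scipy)
        assert res["Z"] == pytest.approx(z_scipy, abs=0.1)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 14)
        r1 = ranksum_test(x, y)
        r2 = ranksum_test(np.exp(x), np.exp(y))
        assert r1["Z"] == pytest.approx(r2["Z"])
        assert r1["ranksum"] == r2["ranksum"]

    def test_kruskal_matches_hand_ranks(self):
        # 9 values, no ties: H computed from hand-assigned ranks
        a, b, c = [1.0, 4.0, 7.0], [2.0, 5.0, 8.0], [3.0, 6.0, 9.0]
        ranks = {1: 1, 4: 4, 7: 7, 2: 2, 5: 5, 8: 8, 3: 3, 6: 6, 9: 9}
        n, k = 9, 3
        R = [sum(ranks[v] for v in g) for g in (a, b, c)]
        H_hand = 12 / (n * (n + 1)) * sum(r**2 / 3 for r in R) - 3 * (n + 1)
        res = kruskal_wallis(a, b, c)
        assert res["H"] == pytest.approx(H_hand)
        assert res["df"] == k - 1

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            ranksum_test([1.0, 2.0], [3.0, 4.0, 5.0])


class TestThresholdRegression:
    def _cohort(self, rng, n=105, b_age=0.6, b_gap=0.3, noise=18.0):
        age = rng.uniform(20, 95, n)
        gap = np.clip(rng.normal(20, 20, n), 0, None)
        thr = 5.0 + b_age * age + b_gap * gap + rng.normal(0, noise, n)
        return pd.DataFrame({"threshold_250": thr, "age": age, "gap": gap})

    def test_noiseless_exact_recovery(self, rng):
        df = self._cohort(rng, noise=0.0)
        res = fit_threshold_regression(df)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["coefficients"].loc["age", "coef"] == pytest.approx(0.6)
        assert res["coefficients"].loc["gap", "coef"] == pytest.approx(0.3)

    def test_added_variable_data_regression_slope(self, rng):
        df = self._cohort(rng)
        res = fit_threshold_regression(df)
        av = res["added_variable"]["gap"]
        slope = np.polyfit(av["x_adj"], av["y_adj"], 1)[0]
        assert slope == pytest.approx(res["coefficients"].loc["gap", "coef"], rel=1e-6)

    def test_weak_effect_cohort_r2_calibration(self):
        # human-like cohort (18 young controls + 87 older cases): weak age and
        # gap effects give r^2 near 0.18 on average at n = 105
        r2 = []
        for s in range(100):
            gen = np.random.default_rng(s)
            age = np.concatenate([gen.uniform(5, 70, 18), gen.uniform(55, 95, 87)])
            gap = np.clip(np.concatenate(
                [gen.normal(10, 18, 18), gen.normal(26, 27, 87)]), 0, None)
            thr = 10 + 0.38 * age + 0.26 * gap + gen.normal(0, 23.0, 105)
            df = pd.DataFrame({"threshold_250": thr, "age": age, "gap": gap})
            r2.append(fit_threshold_regression(df)["r_squared"])
        assert np.mean(r2) == pytest.approx(0.18, abs=0.05)

    def test_permuted_response_null(self, rng):
        df = self._cohort(rng, b_age=0.0, b_gap=0.0)
        ps = []
        for _ in range(100):
            d = df.copy()
            d["threshold_250"] = rng.permutation(d["threshold_250"].to_numpy())
            ps.append(fit_threshold_regression(d)["f_pvalue"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_collinearity_flagged(self, rng):
        df = self._cohort(rng)
        df["gap"] = df["age"] * 2.0
        with pytest.raises(ValueError, match="collinear|rank|condition"):
            fit_threshold_regression(df)

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="age"):
            fit_threshold_regression(pd.DataFrame({"threshold_250": [1.0], "gap": [1.0]}))
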