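"""Standardization, RTM models, and the OLS/LMM covariate regressions."""

import numpy as np
import pandas as pd
import pytest

from cardiofit.regression_analysis import (
    MixedEffectsModel,
    OLSChangeModel,
    RegressionSpec,
    RTMChangeModel,
    RTMFinalValueModel,
    rtm_null_slopes,
    standardize,
)


class TestStandardize:
    def test_zscore_uses_population_sd(self):
        out = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), ["x"])
        assert out["x"].to_numpy() == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_zscored_column_is_unchanged_by_rezscoring(self, rng):
        df = pd.DataFrame({"x": rng.normal(5, 2, size=50)})
        once = standardize(df, ["x"])
        twice = standardize(once, ["x"])
        assert twice["x"].to_numpy() == pytest.approx(once["x"].to_numpy(), abs=1e-12)

    def test_centering_preserves_pairwise_differences(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20)})
        out = standardize(df, ["x"], mode="center")
        assert np.diff(out["x"]) == pytest.approx(np.diff(df["x"]), abs=1e-12)
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero SD"):
            standardize(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), ["x"])


def _rtm_frame(day1, day2, day3):
    rows = []
    for i, (a, b, c) in enumerate(zip(day1, day2, day3)):
        rows += [
            {"participant": f"P{i}", "day": "1", "value": a},
            {"participant": f"P{i}", "day": "2", "value": b},
            {"participant": f"P{i}", "day": "3", "value": c},
        ]
    return pd.DataFrame(rows)


class TestRTMModels:
    def test_final_value_perfect_personal_clustering(self):
        # day-3 value equals the personal two-day average: perfect fit
        v = np.array([1.0, 1.2, 0.9, 1.5, 1.1])
        df = _rtm_frame(v, v, v)
        res = RTMFinalValueModel(df).fit()
        assert res.adj_r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_constructed_change_slope(self):
        # Δ₁₃ = −k (day1 − pop mean) exactly → slope −k, r² = 1
        k = 0.6
        d1 = np.array([1.0, 1.3, 0.8, 1.6, 1.05, 0.95])
        pop = np.concatenate([d1, d1, d1]).mean()  # construct day2 = day1 first
        d3 = d1 - k * (d1 - d1.mean())
        df = _rtm_frame(d1, d1, d3)
        pop = df["value"].mean()
        d3 = d1 - k * (d1 - pop)
        df = _rtm_frame(d1, d1, d3)
        # iterate once more so the population mean includes the new day-3 values
        for _ in range(60):
            pop = df["value"].mean()
            d3 = d1 - k * (d1 - pop)
            df = _rtm_frame(d1, d1, d3)
        res = RTMChangeModel(df).fit()
        assert res.slope == pytest.approx(-k, abs=1e-6)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_no_noise_no_effect_gives_zero_slope(self):
        d = np.array([1.0, 1.2, 0.9, 1.4])
        res = RTMChangeModel(_rtm_frame(d, d, d)).fit()
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_rejected(self):
        ones = np.ones(5)
        with pytest.raises(ValueError):
            RTMFinalValueModel(_rtm_frame(ones, ones, ones)).fit()

    def test_null_cohort_slopes_match_covariance_algebra(self, rng):
        # θ_ij = μ + α_i + ε_ij with no effect: closed-form slopes
        n, sa, se = 800, 0.10, 0.05
        alpha = rng.normal(0, sa, n)
        eps = rng.normal(0, se, (3, n))
        days = 1.13 * (1 + alpha + eps)
        df = _rtm_frame(*days)
        change = RTMChangeModel(df).fit()
        final = RTMFinalValueModel(df).fit()
        theory = rtm_null_slopes(sa, se)
        assert change.slope == pytest.approx(theory["change"], abs=3 * change.bse["deviation"])
        assert final.slope > 0
        assert final.slope == pytest.approx(theory["final_value"], abs=3 * final.bse["deviation"])


class TestOLSOracle:
    def test_matches_normal_equations(self, rng):
        # the OLS backend agrees with a brute-force solver to 1e-10
        import statsmodels.api as sm

        for _ in range(10):
            X = rng.normal(size=(25, 3))
            y = rng.normal(size=25)
            Xc = np.column_stack([np.ones(25), X])
            beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
            fit = sm.OLS(y, Xc).fit()
            assert fit.params == pytest.approx(beta, abs=1e-10)

    def test_adjusted_r2_reported_unclipped_and_matches_definition(self):
        # small-n pure-noise fit: adjusted r² is negative and must be reported
        # as computed, never clipped at zero
        rng = np.random.default_rng(1)
        n = 12
        d = pd.DataFrame({
            "delta": rng.normal(size=n),
            "age": rng.normal(55, 4, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "dBMI": rng.normal(0, 1, n),
        })
        res = OLSChangeModel(d, RegressionSpec(config="A")).fit()
        # recompute adjusted r² by hand on the same standardized data
        z = standardize(d, ["delta", "age", "sex", "dBMI"])
        X = np.column_stack([np.ones(n), z[["age", "sex", "dBMI"]].to_numpy()])
        y = z["delta"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        ss_res = np.sum((y - X @ beta) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        adj = 1 - (1 - (1 - ss_res / ss_tot)) * (n - 1) / (n - 3 - 1)
        assert res.adj_r2 == pytest.approx(adj, abs=1e-10)
        assert res.adj_r2 < 0


class TestOLSChangeModel:
    def test_config_regressor_sets(self):
        assert RegressionSpec(config="A").regressors == ("age", "sex", "BMI")
        assert RegressionSpec(config="B").regressors == ("age", "sex", "BMI", "SV")
        assert RegressionSpec(config="C").regressors == ("age", "sex", "BMI", "VO2max")
        assert RegressionSpec(config="D").regressors == ("age", "sex", "BMI", "SV", "VO2max")
        # the alternative labeling swaps B and C
        assert RegressionSpec(config="B", labeling="methods").regressors == (
            "age", "sex", "BMI", "VO2max")

    def test_exact_linear_combination_fits_perfectly(self, rng):
        n = 20
        d = pd.DataFrame({
            "age": rng.normal(55, 4, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "dBMI": rng.normal(0, 1, n),
        })
        d["delta"] = 2.0 * d["dBMI"] - 0.5 * d["age"] + 3.0
        res = OLSChangeModel(d, RegressionSpec(config="A")).fit()
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert res.f_pvalue < 1e-12

    def test_noise_response_gives_near_zero_adj_r2(self, rng):
        n = 200
        d = pd.DataFrame({
            "delta": rng.normal(size=n),
            "age": rng.normal(55, 4, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "dBMI": rng.normal(0, 1, n),
        })
        res = OLSChangeModel(d, RegressionSpec(config="A")).fit()
        assert abs(res.adj_r2) < 0.08

    def test_rank_deficiency_names_columns(self, rng):
        n = 15
        d = pd.DataFrame({
            "delta": rng.normal(size=n),
            "age": rng.normal(55, 4, n),
            "sex": rng.integers(0, 2, n).astype(float),
        })
        d["dBMI"] = 2.0 * d["age"]  # collinear after z-scoring
        with pytest.raises(ValueError, match="collinear"):
            OLSChangeModel(d, RegressionSpec(config="A")).fit()

    def test_too_few_rows_rejected(self):
        d = pd.DataFrame({"delta": [0.1, 0.2], "age": [50, 60],
                          "sex": [0, 1], "dBMI": [0.5, -0.5]})
        with pytest.raises(ValueError):
            OLSChangeModel(d, RegressionSpec(config="A")).fit()


def _lmm_frame(rng, n=60, days=3, group_sd=1.0, noise_sd=0.1, sv_coef=0.0):
    rows = []
    intercepts = rng.normal(0, group_sd, n)
    for i in range(n):
        for d in range(days):
            sv = rng.normal(85, 20)
            rows.append({
                "participant": f"P{i}",
                "age": rng.normal(55, 4),
                "sex": float(i % 2),
                "BMI": rng.normal(28, 3),
                "SV": sv,
                "VO2max": rng.normal(36, 7),
                "value": intercepts[i] + sv_coef * sv + rng.normal(0, noise_sd),
            })
    return pd.DataFrame(rows)


class TestMixedEffectsModel:
    def test_pure_random_intercepts(self, rng):
        # response is intercepts + tiny noise: group variance dominates,
        # covariate coefficients are near zero on the standardized scale
        # (chance correlations scale as 1/sqrt(n_groups))
        df = _lmm_frame(rng, n=150, group_sd=1.0, noise_sd=0.05)
        res = MixedEffectsModel(df, RegressionSpec(config="A", estimator="lmm")).fit()
        assert res.group_var > 10 * res.resid_var
        for term in ("age", "sex", "BMI"):
            assert abs(res.params[term]) < 0.3
        assert res.n_groups == 150
        assert res.group_size == pytest.approx(3.0)

    def test_pure_covariate_effect(self, rng):
        # response = 2·SV with no grouping variance: the SV coefficient on the
        # standardized scale is SD(2·SV)/SD(value) ≈ corr = 1, group var ≈ 0
        df = _lmm_frame(rng, n=40, group_sd=0.0, noise_sd=1e-6, sv_coef=2.0)
        res = MixedEffectsModel(df, RegressionSpec(config="B", estimator="lmm")).fit()
        # dependent is z-scored, SV only centered: coefficient = 2/SD(value)
        expected = 2.0 / df["value"].std(ddof=0)
        assert res.params["SV"] == pytest.approx(expected, rel=1e-2)
        assert res.group_var < 0.01

    def test_zero_group_variance_recovered(self, rng):
        df = _lmm_frame(rng, n=50, group_sd=0.0, noise_sd=1.0)
        res = MixedEffectsModel(df, RegressionSpec(config="A", estimator="lmm")).fit()
        assert res.group_var < 0.05  # standardized scale

    def test_repeated_measures_required(self, rng):
        df = _lmm_frame(rng, n=10, days=1)
        with pytest.raises(ValueError, match="repeated"):
            MixedEffectsModel(df, RegressionSpec(config="A")).fit()
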