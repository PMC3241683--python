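"""Mixed-model machinery: standardization, REML, df rule, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.special import expit

from gmlpath import (
    ModelSpec,
    SeparationError,
    ZeroVarianceError,
    collinearity_check,
    fit_mixed,
    random_effect_ci,
    residualized_interaction,
    standardize,
    variance_explained,
)
from gmlpath.mixedfit import CategoricalTerm, LinearTerm, QuadraticTerm


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        out, params = standardize(df, ["a"])
        assert out["a"].mean() == pytest.approx(0.0)
        assert out["a"].std(ddof=1) == pytest.approx(1.0)

    def test_constant_column_raises(self):
        with pytest.raises(ZeroVarianceError):
            standardize(pd.DataFrame({"a": [5.0, 5.0, 5.0]}), ["a"])

    def test_inverse_recovers_original(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 7, 40), "b": rng.uniform(0, 2, 40)})
        out, params = standardize(df, ["a", "b"])
        back = params.inverse(out)
        np.testing.assert_allclose(back[["a", "b"]], df[["a", "b"]], rtol=1e-12)

    def test_untouched_columns_preserved(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "keep": list("abcdefghij")})
        out, _ = standardize(df, ["a"])
        assert (out["keep"] == df["keep"]).all()


class TestResidualizedInteraction:
    def test_orthogonal_to_main_effects_and_unit_sd(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        df, _ = standardize(df, ["a", "b"])
        col = residualized_interaction(df, "a", "b")
        assert abs(np.corrcoef(col, df["a"])[0, 1]) < 1e-12
        assert abs(np.corrcoef(col, df["b"])[0, 1]) < 1e-12
        assert col.std(ddof=1) == pytest.approx(1.0)

    def test_matches_hand_ols_residuals(self):
        a = np.array([-1.0, 0.0, 1.0, 2.0])
        b = np.array([1.0, -1.0, 1.0, -1.0])
        df = pd.DataFrame({"a": a, "b": b})
        df, _ = standardize(df, ["a", "b"])
        col = residualized_interaction(df, "a", "b")
        # hand OLS: regress product on [1, a, b] via the normal equations
        za, zb = df["a"].to_numpy(), df["b"].to_numpy()
        prod = za * zb
        design = np.column_stack([np.ones(4), za, zb])
        beta = np.linalg.solve(design.T @ design, design.T @ prod)
        resid = prod - design @ beta
        expected = resid / resid.std(ddof=1)
        np.testing.assert_allclose(col, expected, atol=1e-12)

    def test_collinear_product_raises(self):
        df = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0], "b": [1.0, -1.0, 1.0, -1.0]})
        # a*a is a constant for a in {-1, 1}
        with pytest.raises(ZeroVarianceError):
            residualized_interaction(df, "a", "b")


def balanced_one_way(rng, k=12, m=5, sd_b=2.0, sd_e=1.0):
    g = np.repeat(np.arange(k), m)
    b = rng.normal(0, sd_b, k)
    y = 3.0 + b[g] + rng.normal(0, sd_e, k * m)
    return pd.DataFrame({"y": y, "g": g.astype(str)}), k, m


class TestGaussianFit:
    def test_noise_free_line_is_interpolated(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [1.0, 3.0, 5.0, 7.0]})
        fit = fit_mixed(ModelSpec("y", ["x"]), df)
        assert fit.coefficient("x").beta == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficient("(Intercept)").beta == pytest.approx(1.0, abs=1e-10)

    def test_reml_matches_anova_closed_form_in_balanced_design(self, rng):
        df, k, m = balanced_one_way(rng)
        fit = fit_mixed(ModelSpec("y", [], random_nesting=("g",)), df)
        means = df.groupby("g")["y"].mean()
        grand = means.mean()
        ms_within = ((df["y"] - means[df["g"]].to_numpy()) ** 2).sum() / (k * m - k)
        ms_between = m * ((means - grand) ** 2).sum() / (k - 1)
        sd_b = np.sqrt((ms_between - ms_within) / m)
        assert fit.random_sd[0].sd == pytest.approx(sd_b, rel=1e-5)
        assert fit.sigma_resid == pytest.approx(np.sqrt(ms_within), rel=1e-5)

    def test_matches_statsmodels_mixedlm(self, rng):
        df, k, m = balanced_one_way(rng)
        df["x"] = rng.normal(size=len(df))
        df["y"] = df["y"] + 0.5 * df["x"]
        fit = fit_mixed(ModelSpec("y", ["x"], random_nesting=("g",)), df)
        ref = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=True)
        assert fit.coefficient("x").beta == pytest.approx(ref.params["x"], abs=1e-5)
        assert fit.coefficient("(Intercept)").beta == pytest.approx(
            ref.params["Intercept"], abs=1e-5
        )
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)
        assert fit.random_sd[0].sd == pytest.approx(
            np.sqrt(ref.cov_re.iloc[0, 0]), rel=1e-3
        )

    def test_no_random_terms_equals_ols_exactly(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["y"] = 1.0 + 2.0 * df["x"] + rng.normal(size=30)
        fit = fit_mixed(ModelSpec("y", ["x"]), df)
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert fit.coefficient("x").beta == pytest.approx(ols.params["x"], abs=1e-12)
        assert fit.coefficient("x").se == pytest.approx(ols.bse["x"], rel=1e-10)
        assert fit.coefficient("x").df == len(df) - 2

    def test_standardized_coefficient_equivariance(self, rng):
        n = 120
        g = np.repeat(np.arange(12), 10)
        df = pd.DataFrame(
            {"x": rng.normal(2, 3, n), "g": g.astype(str)}
        )
        df["y"] = 5 + 1.7 * df["x"] + rng.normal(0, 2, n)[g] + rng.normal(0, 1, n)
        raw = fit_mixed(ModelSpec("y", ["x"], random_nesting=("g",)), df)
        std, params = standardize(df, ["x", "y"])
        zfit = fit_mixed(ModelSpec("y", ["x"], random_nesting=("g",)), std)
        sx = params.params["x"][1]
        sy = params.params["y"][1]
        assert zfit.coefficient("x").beta == pytest.approx(
            raw.coefficient("x").beta * sx / sy, abs=1e-6
        )

    def test_rows_with_missing_values_are_dropped_and_counted(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20), "y": rng.normal(size=20)})
        df.loc[3, "x"] = np.nan
        df.loc[7, "y"] = np.nan
        fit = fit_mixed(ModelSpec("y", ["x"]), df)
        assert fit.n_dropped == 2
        assert fit.n_obs == 18


class TestContainmentDf:
    def test_group_level_terms_get_group_level_df(self, rng):
        # 20 nests x 4 nestlings; timing constant per nest, tarsus varies
        nests = np.repeat(np.arange(20), 4)
        timing = rng.normal(size=20)[nests]
        tarsus = rng.normal(size=80)
        y = 0.5 * timing + 0.3 * tarsus + rng.normal(0, 2, 20)[nests] + rng.normal(size=80)
        df = pd.DataFrame(
            {"y": y, "timing": timing, "tarsus": tarsus, "nest": nests.astype(str)}
        )
        fit = fit_mixed(ModelSpec("y", ["timing", "tarsus"], random_nesting=("nest",)), df)
        # nest level: 20 - 1 - 1 nest-level term = 18
        assert fit.coefficient("timing").df == 18
        # observation level: 80 - 20 - 1 observation-level term = 59
        assert fit.coefficient("tarsus").df == 59

    def test_group_constant_model_collapses_to_group_level_ols(self, rng):
        # response and predictor both constant within groups: the fit must
        # equal one-row-per-group OLS (replicated rows carry no information)
        nests = np.repeat(np.arange(30), 3)
        x = rng.normal(size=30)
        y30 = 1.0 + 0.8 * x + rng.normal(0, 1, 30)
        df = pd.DataFrame(
            {"y": y30[nests], "x": x[nests], "nest": nests.astype(str)}
        )
        fit = fit_mixed(ModelSpec("y", ["x"], random_nesting=("nest",)), df)
        ols = sm.OLS(y30, sm.add_constant(x)).fit()
        assert fit.coefficient("x").beta == pytest.approx(ols.params[1], abs=1e-10)
        assert fit.coefficient("x").se == pytest.approx(ols.bse[1], rel=1e-8)
        assert fit.coefficient("x").df == 28


class TestDiagnostics:
    def test_orthogonal_predictors_not_flagged(self, rng):
        n = 400
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        df["y"] = df["a"] + df["b"] + rng.normal(size=n)
        fit = fit_mixed(ModelSpec("y", ["a", "b"]), df)
        report = collinearity_check(fit)
        assert report.ok
        assert abs(report.correlations.loc["a", "b"]) < 0.2

    def test_duplicated_predictor_flags_singularity(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"]
        df["y"] = df["a"] + rng.normal(size=50)
        fit = fit_mixed(ModelSpec("y", ["a", "b"]), df)
        report = collinearity_check(fit)
        assert report.singular or report.flagged

    def test_correlated_predictors_flagged(self, rng):
        n = 500
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        df = pd.DataFrame({"a": a, "b": b})
        df["y"] = df["a"] + rng.normal(size=n)
        fit = fit_mixed(ModelSpec("y", ["a", "b"]), df)
        report = collinearity_check(fit)
        assert any({p[0], p[1]} == {"a", "b"} for p in report.flagged)

    def test_variance_explained_perfect_and_null(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=40)})
        df["y"] = 2 * df["x"] + 1
        assert variance_explained(ModelSpec("y", ["x"]), df) == pytest.approx(1.0)
        df["y2"] = rng.normal(size=40)
        with pytest.warns(UserWarning):
            r2 = variance_explained(ModelSpec("y2", []), df)
        assert r2 == 0.0

    def test_variance_explained_equals_squared_correlation(self, rng):
        n = 200
        df = pd.DataFrame({"x": rng.normal(size=n)})
        df["y"] = df["x"] + rng.normal(size=n)
        r2 = variance_explained(ModelSpec("y", ["x"]), df)
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        expected = np.corrcoef(df["y"], ols.fittedvalues)[0, 1] ** 2
        assert r2 == pytest.approx(expected, abs=1e-10)


class TestRandomEffectCI:
    def _fit(self, rng, sd_b, k=30, m=8):
        g = np.repeat(np.arange(k), m)
        y = rng.normal(0, sd_b, k)[g] + rng.normal(0, 1.0, k * m)
        df = pd.DataFrame({"y": y, "g": g.astype(str)})
        return fit_mixed(ModelSpec("y", [], random_nesting=("g",)), df)

    def test_interval_contains_point_estimate(self, rng):
        fit = self._fit(rng, sd_b=2.0)
        (info,) = random_effect_ci(fit)
        assert info["ci_low"] <= info["sd"] <= info["ci_high"]

    def test_zero_group_variance_rarely_supported(self):
        supported = 0
        for seed in range(20):
            rng = np.random.default_rng(9000 + seed)
            fit = self._fit(rng, sd_b=0.0)
            (info,) = random_effect_ci(fit)
            supported += info["supported"]
        assert supported <= 2  # >= 90% "not supported"

    def test_large_group_variance_supported(self):
        supported = 0
        for seed in range(20):
            rng = np.random.default_rng(9100 + seed)
            fit = self._fit(rng, sd_b=5.0)
            (info,) = random_effect_ci(fit)
            supported += info["supported"]
        assert supported == 20


class TestBinomial:
    def test_constant_response_raises_separation(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30), "y": np.ones(30)})
        with pytest.raises(SeparationError):
            fit_mixed(ModelSpec("y", ["x"], family="binomial-logit"), df)

    def test_perfectly_separating_predictor_raises(self):
        x = np.linspace(-2, 2, 40)
        df = pd.DataFrame({"x": x, "y": (x > 0).astype(float)})
        with pytest.raises(SeparationError):
            fit_mixed(ModelSpec("y", ["x"], family="binomial-logit"), df)

    def test_single_binary_predictor_equals_log_odds_ratio(self):
        # 2x2 table: exposure 0 -> 30/70 survive, exposure 1 -> 55/45
        rows = (
            [(0, 1)] * 30 + [(0, 0)] * 70 + [(1, 1)] * 55 + [(1, 0)] * 45
        )
        df = pd.DataFrame(rows, columns=["x", "y"]).astype(float)
        fit = fit_mixed(ModelSpec("y", ["x"], family="binomial-logit"), df)
        lor = np.log((55 / 45) / (30 / 70))
        assert fit.coefficient("x").beta == pytest.approx(lor, abs=1e-5)

    def test_matches_statsmodels_glm_without_random_effects(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(-0.4 + 0.9 * x))
        df = pd.DataFrame({"x": x, "y": y.astype(float)})
        fit = fit_mixed(ModelSpec("y", ["x"], family="binomial-logit"), df)
        ref = sm.GLM(df["y"], sm.add_constant(df["x"]), family=sm.families.Binomial()).fit()
        assert fit.coefficient("x").beta == pytest.approx(ref.params["x"], abs=1e-5)
        assert fit.coefficient("x").se == pytest.approx(ref.bse["x"], rel=1e-3)

    def test_random_intercepts_recover_simulated_slope(self):
        rng = np.random.default_rng(77)
        k, m = 40, 12
        g = np.repeat(np.arange(k), m)
        b = rng.normal(0, 1.0, k)
        x = rng.normal(size=k * m)
        y = rng.binomial(1, expit(-0.2 + 0.8 * x + b[g]))
        df = pd.DataFrame({"x": x, "y": y.astype(float), "g": g.astype(str)})
        fit = fit_mixed(
            ModelSpec("y", ["x"], family="binomial-logit", random_nesting=("g",)), df
        )
        c = fit.coefficient("x")
        assert abs(c.beta - 0.8) < 3 * c.se
        assert 0.4 < fit.random_sd[0].sd < 1.8


class TestTermTypes:
    def test_quadratic_term_contributes_two_columns(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=100)})
        df["y"] = 1 + 0.5 * df["x"] - 0.3 * df["x"] ** 2 + rng.normal(0, 0.1, 100)
        fit = fit_mixed(ModelSpec("y", [QuadraticTerm("x")]), df)
        assert fit.coefficient("x").beta == pytest.approx(0.5, abs=0.05)
        assert fit.coefficient("x^2").beta == pytest.approx(-0.3, abs=0.05)

    def test_categorical_reference_level(self, rng):
        df = pd.DataFrame(
            {"year": ["2008"] * 30 + ["2009"] * 30, "y": rng.normal(size=60)}
        )
        df.loc[df["year"] == "2009", "y"] += 2.0
        fit = fit_mixed(
            ModelSpec("y", [CategoricalTerm("year", reference="2008")]), df
        )
        assert fit.coefficient("year[2009]").beta == pytest.approx(2.0, abs=0.6)
        with pytest.raises(ValueError, match="reference level"):
            fit_mixed(ModelSpec("y", [CategoricalTerm("year", reference="1999")]), df)

    def test_response_among_fixed_terms_rejected(self):
        with pytest.raises(ValueError, match="response"):
            ModelSpec("y", ["y", "x"])

    def test_repeated_nesting_rejected(self):
        with pytest.raises(ValueError, match="repeat"):
            ModelSpec("y", ["x"], random_nesting=("g", "g"))
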