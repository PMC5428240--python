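"""AICc arithmetic, mixed-model fits, model selection and descriptive tests."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import gammaln

import beeforage as bf
from beeforage.inference import (
    ModelSpec,
    fit_gaussian_lmm,
    fit_poisson_glmm,
)


def simulate_gaussian(n=500, slope=0.5, colony_sd=0.0, resid_sd=1.0, seed=0,
                      response="nectar_rate"):
    rng = np.random.default_rng(seed)
    colony = rng.choice([f"C{i}" for i in range(5)], size=n)
    u = dict(zip([f"C{i}" for i in range(5)], rng.normal(0, colony_sd, 5)))
    x = rng.uniform(0, 10, n)
    y = 1.0 + slope * x + np.array([u[c] for c in colony]) + rng.normal(0, resid_sd, n)
    return pd.DataFrame({"colony_id": colony, "colony_age": x, response: y})


class TestAicc:
    def test_closed_form(self):
        assert bf.aicc(-40.0, 3, 20) == pytest.approx(87.5)

    def test_converges_to_aic_for_large_n(self):
        aic = -2 * (-40.0) + 2 * 3
        assert abs(bf.aicc(-40.0, 3, 10 ** 6) - aic) < 1e-3

    def test_zero_parameters(self):
        assert bf.aicc(-40.0, 0, 10) == pytest.approx(80.0)

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(bf.EstimationError):
            bf.aicc(-40.0, 5, 6)


class TestGaussianLmm:
    def test_matches_statsmodels_mixedlm(self):
        """Independent ML fit of the same model via statsmodels."""
        data = simulate_gaussian(n=200, colony_sd=0.8, seed=4)
        spec = ModelSpec("nectar_rate", ("colony_age",), family="gaussian_identity")
        mine = fit_gaussian_lmm(data, spec)
        ref = sm.MixedLM.from_formula("nectar_rate ~ colony_age", groups="colony_id",
                                      data=data).fit(reml=False)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert mine.params["intercept"] == pytest.approx(ref.params["Intercept"], abs=1e-4)
        assert mine.params["colony_age"] == pytest.approx(ref.params["colony_age"], abs=1e-5)
        assert mine.bse["colony_age"] == pytest.approx(ref.bse["colony_age"], rel=1e-3)

    def test_zero_colony_variance_reduces_to_ols(self):
        data = simulate_gaussian(n=120, colony_sd=0.0, seed=5)
        spec = ModelSpec("nectar_rate", ("colony_age",), family="gaussian_identity")
        mine = fit_gaussian_lmm(data, spec)
        ols = sm.OLS(data["nectar_rate"], sm.add_constant(data["colony_age"])).fit()
        if mine.singular:
            assert mine.loglik == pytest.approx(ols.llf, abs=1e-6)
        else:  # variance ratio estimated > 0: must still dominate OLS
            assert mine.loglik >= ols.llf - 1e-6

    def test_slope_recovery(self):
        data = simulate_gaussian(n=500, slope=0.5, colony_sd=0.0, seed=6)
        spec = ModelSpec("nectar_rate", ("colony_age",), family="gaussian_identity")
        fit = fit_gaussian_lmm(data, spec)
        assert abs(fit.params["colony_age"] - 0.5) <= 3 * fit.bse["colony_age"]

    def test_constant_response_gives_zero_slope(self):
        data = simulate_gaussian(n=60, seed=7)
        data["nectar_rate"] = 2.0
        spec = ModelSpec("nectar_rate", ("colony_age",), family="gaussian_identity")
        fit = fit_gaussian_lmm(data, spec)
        assert fit.params["colony_age"] == pytest.approx(0.0, abs=1e-8)
        assert np.isfinite(fit.loglik)

    def test_sqrt_family_transforms_response(self):
        data = simulate_gaussian(n=100, seed=8)
        data["mean_bout_duration"] = (2.0 + 0.3 * data["colony_age"]) ** 2
        spec = ModelSpec("mean_bout_duration", ("colony_age",), family="gaussian_sqrt")
        fit = fit_gaussian_lmm(data, spec)
        assert fit.params["colony_age"] == pytest.approx(0.3, abs=1e-6)


def glmer_fixture():
    """Deterministic Poisson dataset; reference values below were produced
    by an independent adaptive-quadrature fit (lme4::glmer, nAGQ=15)."""
    rng = np.random.default_rng(42)
    n = 60
    colony = np.repeat(["C1", "C2", "C3", "C4", "C5"], 12)
    u = {"C1": 0.3, "C2": -0.2, "C3": 0.0, "C4": 0.15, "C5": -0.25}
    lpi = np.round(rng.uniform(0.5, 15.0, n), 2)
    eta = 1.2 + 0.05 * lpi + np.array([u[c] for c in colony])
    y = rng.poisson(np.exp(eta))
    return pd.DataFrame({"colony_id": colony, "lpi": lpi, "days_foraged": y})


GLMER_REF = {  # glmer(y ~ lpi + (1|colony), family=poisson, nAGQ=15)
    "loglik_devscale": -32.767483,  # lme4 reports against the saturated model
    "intercept": 1.12493573, "lpi": 0.05861031,
    "se_intercept": 0.16162091, "se_lpi": 0.01485249,
    "sigma": 0.161020,
}


class TestPoissonGlmm:
    def test_matches_independent_quadrature_fit(self):
        data = glmer_fixture()
        fit = fit_poisson_glmm(data, ModelSpec("days_foraged", ("lpi",)))
        assert fit.params["intercept"] == pytest.approx(GLMER_REF["intercept"], abs=1e-3)
        assert fit.params["lpi"] == pytest.approx(GLMER_REF["lpi"], abs=1e-4)
        assert fit.bse["intercept"] == pytest.approx(GLMER_REF["se_intercept"], abs=1e-3)
        assert fit.bse["lpi"] == pytest.approx(GLMER_REF["se_lpi"], abs=1e-4)
        assert math.sqrt(fit.re_var) == pytest.approx(GLMER_REF["sigma"], abs=2e-3)
        # lme4's GLMM log-likelihood is measured against the saturated model
        y = data["days_foraged"].to_numpy(float)
        ylog = y * np.log(np.where(y > 0, y, 1.0))
        saturated = float(np.sum(ylog - y - gammaln(y + 1)))
        assert fit.loglik - saturated == pytest.approx(
            GLMER_REF["loglik_devscale"], abs=1e-3)

    def test_no_colony_variance_reduces_to_poisson_glm(self):
        rng = np.random.default_rng(1)
        n = 200
        data = pd.DataFrame({
            "colony_id": rng.choice(["C1", "C2", "C3"], n),
            "lpi": rng.uniform(0, 15, n),
        })
        data["days_foraged"] = rng.poisson(np.exp(1.0 + 0.05 * data["lpi"]))
        fit = fit_poisson_glmm(data, ModelSpec("days_foraged", ("lpi",)))
        glm = sm.GLM(data["days_foraged"], sm.add_constant(data["lpi"]),
                     family=sm.families.Poisson()).fit()
        assert fit.loglik >= glm.llf - 1e-6
        if fit.singular:
            assert fit.loglik == pytest.approx(glm.llf, abs=1e-5)

    def test_lpi_coefficient_recovery_with_colony_effects(self):
        rng = np.random.default_rng(9)
        n = 500
        colonies = [f"C{i}" for i in range(5)]
        u = dict(zip(colonies, rng.normal(0, 0.2, 5)))
        data = pd.DataFrame({
            "colony_id": rng.choice(colonies, n),
            "lpi": rng.uniform(0, 16, n),
        })
        eta = 1.7 + 0.06 * data["lpi"] + np.array([u[c] for c in data["colony_id"]])
        data["days_foraged"] = rng.poisson(np.exp(eta))
        fit = fit_poisson_glmm(data, ModelSpec("days_foraged", ("lpi",)))
        assert abs(fit.params["lpi"] - 0.06) <= 2 * fit.bse["lpi"]

    def test_non_count_response_rejected(self):
        data = glmer_fixture()
        data["days_foraged"] = data["days_foraged"] + 0.5
        with pytest.raises(bf.EstimationError):
            fit_poisson_glmm(data, ModelSpec("days_foraged", ("lpi",)))


class TestComparisonTable:
    def test_delta_from_supplied_aicc_values(self):
        """Worked example: second-lowest candidate sits 1.74 above the best."""
        table = bf.build_comparison_table(
            ["basic", "worker_age", "worker_mass", "colony_age", "experience",
             "best+lpi"],
            [-164.33, -162.59, -161.82, -161.96, -162.54, -163.33])
        deltas = dict(zip(table["model"], table["delta_aicc"]))
        assert deltas["worker_age"] == pytest.approx(1.74)
        assert deltas["basic"] == 0.0
        assert (table["delta_aicc"] >= 0).all()
        assert (table["delta_aicc"] == 0).sum() == 1

    def test_strong_covariate_beats_basic_and_lpi_rejected(self):
        """Colony-age-driven response: colony age selected, LPI adds nothing."""
        rng = np.random.default_rng(21)
        wins = 0
        for rep in range(10):
            n = 60
            colonies = [f"C{i}" for i in range(5)]
            data = pd.DataFrame({
                "colony_id": rng.choice(colonies, n),
                "colony_age": rng.uniform(7, 12, n),
                "worker_age": rng.uniform(3, 10, n),
                "worker_mass": rng.normal(180, 25, n),
                "lpi": rng.uniform(0, 16, n),
            })
            sqrt_mean = 8.5 - 0.52 * data["colony_age"] + rng.normal(0, 0.5, n)
            data["mean_bouts_per_day"] = np.clip(sqrt_mean, 0.3, None) ** 2
            table = bf.compare_candidates("mean_bouts_per_day", data,
                                          candidates=("colony_age", "worker_age",
                                                      "worker_mass"))
            best = table.loc[table["best_flag"], "model"].iloc[0]
            if best == "colony_age" and table["lpi_verdict"].iloc[0] == "does_not_predict":
                wins += 1
        assert wins >= 8

    def test_strong_lpi_effect_is_selected(self):
        """Days-foraged response driven by LPI: best+LPI wins by > 2 AICc."""
        rng = np.random.default_rng(22)
        wins = 0
        for rep in range(10):
            n = 60
            colonies = [f"C{i}" for i in range(5)]
            data = pd.DataFrame({
                "colony_id": rng.choice(colonies, n),
                "colony_age": rng.uniform(7, 12, n),
                "worker_age": rng.uniform(3, 10, n),
                "worker_mass": rng.normal(180, 25, n),
                "lpi": rng.uniform(0, 16, n),
            })
            data["days_foraged"] = rng.poisson(np.exp(1.7 + 0.06 * data["lpi"]))
            table = bf.compare_candidates("days_foraged", data)
            if table["lpi_verdict"].iloc[0] == "predicts":
                wins += 1
        assert wins >= 8

    def test_exactly_one_best_flag_and_nonnegative_deltas(self, study_tables):
        table = bf.compare_candidates("mean_bout_duration", study_tables["merged"])
        assert table["best_flag"].sum() == 1
        assert (table["delta_aicc"].dropna() >= 0).all()
        assert np.isclose(table["delta_aicc"].min(), 0.0)


class TestDescriptives:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
        ([1, 2, 3, 4], [40, 30, 20, 10], -1.0),
        ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], 0.8),  # hand-ranked: 1 - 6*4/120
    ])
    def test_spearman(self, x, y, expected):
        rho, _ = bf.spearman_rho(x, y)
        assert rho == pytest.approx(expected)

    def test_spearman_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            bf.spearman_rho([1, 1, 1], [1, 2, 3])

    def test_anova_identical_groups(self):
        F, df1, df2, _ = bf.anova_oneway([[2, 2, 2], [2, 2, 2]])
        assert F == 0.0

    def test_anova_textbook_decomposition(self):
        F, df1, df2, p = bf.anova_oneway([[1, 2, 3], [4, 5, 6]])
        assert F == pytest.approx(13.5)
        assert (df1, df2) == (1, 4)

    def test_anova_degrees_of_freedom(self):
        groups = [list(range(i, i + 3)) for i in range(5)]
        _, df1, _, _ = bf.anova_oneway(groups)
        assert df1 == 4

    def test_mann_whitney_identical_samples(self):
        _, z, _ = bf.mann_whitney_z([1, 2, 3], [1, 2, 3])
        assert z == pytest.approx(0.0)

    def test_mann_whitney_complete_separation(self):
        U, z, _ = bf.mann_whitney_z([1, 2, 3], [10, 11, 12])
        assert U == 0.0

    def test_mann_whitney_u_counts_pairwise_wins(self, rng):
        for _ in range(20):
            a = rng.integers(0, 10, size=rng.integers(2, 8)).astype(float)
            b = rng.integers(0, 10, size=rng.integers(2, 8)).astype(float)
            U, _, _ = bf.mann_whitney_z(a, b)
            brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert U == pytest.approx(brute)
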