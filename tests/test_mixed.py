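"""Mixed models: agreement with independent references and selection logic."""

import math

import numpy as np
import pandas as pd
import pytest

from canishow import (
    ModelFit,
    add_nested_time_columns,
    fit_gaussian_lmm,
    fit_logistic_glmm,
    select_model_aic,
)
from canishow.mixed import _design, _lmm_pieces, _lmm_profile

from helpers import (
    GLMM_ORACLE,
    LMM_ORACLE,
    glmm_oracle_fixture,
    lmm_oracle_fixture,
)


class TestLogisticGlmm:
    def test_matches_frozen_lme4_reference(self):
        """Estimates agree with a 25-node adaptive-quadrature reference fit
        (lme4::glmer) frozen from the same deterministic dataset."""
        fit = fit_logistic_glmm(glmm_oracle_fixture(), "y", ["x"], group="g")
        assert fit.converged
        assert fit.beta == pytest.approx(GLMM_ORACLE["beta"], abs=1e-3)
        assert fit.se == pytest.approx(GLMM_ORACLE["se"], abs=1e-3)
        assert math.sqrt(fit.sigma_u2) == pytest.approx(GLMM_ORACLE["sigma_u"],
                                                        abs=1e-2)
        assert fit.loglik == pytest.approx(GLMM_ORACLE["loglik"], abs=1e-3)

    def test_zero_variance_collapses_to_ordinary_logistic(self):
        """With the random-intercept variance pinned at zero the fit equals
        plain logistic regression (statsmodels GLM as the oracle)."""
        import statsmodels.api as sm

        df = glmm_oracle_fixture()
        fit = fit_logistic_glmm(df, "y", ["x"], group="g", fix_sigma=0.0)
        X = sm.add_constant(df["x"].to_numpy())
        ref = sm.GLM(df["y"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert fit.beta == pytest.approx(ref.params, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse, abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_balanced_null_intercept_near_zero(self):
        rng = np.random.default_rng(5)
        n = 480
        df = pd.DataFrame({
            "y": rng.permutation(np.repeat([0, 1], n // 2)),
            "g": np.repeat([f"p{i}" for i in range(30)], n // 30),
        })
        fit = fit_logistic_glmm(df, "y", [], group="g")
        assert abs(fit.beta[0]) < 0.1

    def test_constant_predictor_is_singular_design(self):
        df = glmm_oracle_fixture().assign(flat=1.0)
        with pytest.raises(ValueError, match="singular design"):
            fit_logistic_glmm(df, "y", ["flat"], group="g")

    def test_non_binary_response_rejected(self):
        df = glmm_oracle_fixture().assign(y=lambda d: d.y + 0.5)
        with pytest.raises(ValueError, match="binary"):
            fit_logistic_glmm(df, "y", ["x"], group="g")

    def test_aic_arithmetic(self):
        fit = fit_logistic_glmm(glmm_oracle_fixture(), "y", ["x"], group="g")
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)


class TestGaussianLmm:
    def test_matches_frozen_lmertest_reference(self):
        """REML estimates, SEs and Satterthwaite df agree with a frozen
        lmerTest::lmer fit of the same deterministic dataset."""
        fit = fit_gaussian_lmm(lmm_oracle_fixture(), "y", ["x"], group="g")
        assert fit.beta == pytest.approx(LMM_ORACLE["beta"], abs=1e-6)
        assert fit.se == pytest.approx(LMM_ORACLE["se"], abs=1e-6)
        assert fit.df == pytest.approx(LMM_ORACLE["df"], abs=0.05)
        assert fit.sigma_u2 == pytest.approx(LMM_ORACLE["sigma_u2"], abs=1e-5)
        assert fit.sigma_e2 == pytest.approx(LMM_ORACLE["sigma_e2"], abs=1e-5)
        assert fit.loglik == pytest.approx(LMM_ORACLE["loglik"], abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(31)
        df = pd.DataFrame({
            "g": np.repeat([f"g{i}" for i in range(15)], 10),
            "x": rng.normal(size=150),
        })
        df["y"] = 0.3 - 0.7 * df.x + np.repeat(rng.normal(0, 0.5, 15), 10) \
            + rng.normal(0, 1.0, 150)
        fit = fit_gaussian_lmm(df, "y", ["x"], group="g")
        ref = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=True,
                                                           method="powell")
        assert ref.converged
        assert fit.beta == pytest.approx(ref.fe_params.to_numpy(), abs=1e-4)
        assert fit.se == pytest.approx(ref.bse_fe.to_numpy(), abs=1e-4)
        assert fit.sigma_e2 == pytest.approx(ref.scale, rel=1e-3)

    def test_gls_optimality_of_fitted_coefficients(self):
        """The fitted coefficients minimize the generalized residual sum of
        squares: any perturbation increases it."""
        df = lmm_oracle_fixture()
        y, X, gidx, names, _ = _design(df, "y", ["x"], "g")
        pieces = _lmm_pieces(y, X, gidx, gidx.max() + 1)
        fit = fit_gaussian_lmm(df, "y", ["x"], group="g")
        lam = fit.sigma_u2 / fit.sigma_e2

        def gen_rss(beta):
            q = 0.0
            for yg, Xg in pieces:
                c = lam / (1.0 + lam * len(yg))
                rg = yg - Xg @ beta
                q += rg @ rg - c * rg.sum() ** 2
            return q

        q_hat = gen_rss(fit.beta)
        assert q_hat < gen_rss(fit.beta + 0.1)
        assert q_hat < gen_rss(fit.beta - 0.1)

    def test_zero_variance_response_rejected(self):
        df = lmm_oracle_fixture().assign(y=1.0)
        with pytest.raises(ValueError, match="zero variance"):
            fit_gaussian_lmm(df, "y", ["x"], group="g")

    def test_ml_vs_reml_loglik_ordering(self):
        df = lmm_oracle_fixture()
        ml = fit_gaussian_lmm(df, "y", ["x"], group="g", reml=False)
        reml = fit_gaussian_lmm(df, "y", ["x"], group="g", reml=True)
        assert ml.method == "ml" and reml.method == "reml"
        assert ml.loglik != reml.loglik


class TestNestedTimeDesign:
    def test_coding(self):
        df = pd.DataFrame({
            "session": [1, 1, 2, 2], "trial": [1, 4, 2, 3],
            "phase": [1, 2, 1, 2], "condition": ["close", "close", "far", "far"],
        })
        out = add_nested_time_columns(df)
        assert out.session2.tolist() == [0, 0, 1, 1]
        assert out.trial_s1.tolist() == [-1.5, 1.5, 0.0, 0.0]
        assert out.trial_s2.tolist() == [0.0, 0.0, -0.5, 0.5]
        assert out.phase2_s1.tolist() == [0, 1, 0, 0]
        assert out.phase2_s2.tolist() == [0, 0, 0, 1]
        assert out.condition_far.tolist() == [0, 0, 1, 1]


def _dummy_fit(loglik, k, rows=(1, 2, 3), method="ml"):
    return ModelFit(family="binomial-logit", names=["(intercept)"],
                    beta=np.zeros(1), se=np.ones(1), stat=np.zeros(1),
                    stat_name="z", p=np.ones(1), df=None, sigma_u2=0.0,
                    sigma_e2=None, loglik=loglik, k_params=k, n=len(rows),
                    rows_index=tuple(rows), converged=True,
                    optimizer="none", method=method)


class TestModelSelection:
    def test_aic_arithmetic_and_tie_rule(self):
        a, b = _dummy_fit(-100.0, 3), _dummy_fit(-100.0, 3)
        cmp_ = select_model_aic([a, b])
        assert cmp_.aic[0] == pytest.approx(206.0)
        assert cmp_.selected == 0  # tie goes to declaration order

    def test_lrt_for_nested_pair(self):
        small, large = _dummy_fit(-105.0, 3), _dummy_fit(-100.0, 5)
        cmp_ = select_model_aic([small, large], nested=[(0, 1)])
        (r,) = cmp_.lrt
        assert r["chi2"] == pytest.approx(10.0)
        assert r["df"] == 2
        from scipy.stats import chi2
        assert r["p"] == pytest.approx(chi2.sf(10.0, 2))

    def test_differing_row_sets_rejected(self):
        with pytest.raises(ValueError, match="differing row sets"):
            select_model_aic([_dummy_fit(-1, 2, rows=(1, 2)),
                              _dummy_fit(-1, 2, rows=(1, 3))])

    def test_mixed_estimation_methods_rejected(self):
        with pytest.raises(ValueError, match="ML and REML"):
            select_model_aic([_dummy_fit(-1, 2), _dummy_fit(-1, 2, method="reml")])

    def test_not_nested_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            select_model_aic([_dummy_fit(-1, 3), _dummy_fit(-1, 2)],
                             nested=[(0, 1)])

    def test_aic_ordering_invariant_to_loglik_shift(self):
        fits = [_dummy_fit(-100.0, 3), _dummy_fit(-98.0, 4), _dummy_fit(-97.5, 5)]
        shifted = [_dummy_fit(f.loglik + 50.0, f.k_params) for f in fits]
        assert (select_model_aic(fits).selected
                == select_model_aic(shifted).selected)
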