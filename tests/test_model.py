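"""Standardization, design build, robust and mixed fits, BIC selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import mfdpm
from mfdpm.design import DESIGN_COLUMNS, INTERACTIONS, design_matrix
from mfdpm.model import (
    FittedBiomarkerModel,
    fit_fixed_robust,
    fit_mixed,
    select_model_bic,
    standardize,
)
from conftest import make_covariates


def _long(values, biomarker="m"):
    n = len(values)
    return mfdpm.validate_cohort(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "visit": 0, "age": np.linspace(50, 60, n), "sex": 0,
                "education": 12.0, "apoe4": 0, "ds": 1,
                "biomarker_id": biomarker, "value": values,
            }
        )
    )


class TestStandardize:
    def test_three_values(self):
        out, table = standardize(_long([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            np.sort(out["value"].to_numpy()), [-1.0, 0.0, 1.0], atol=1e-12
        )
        assert table.loc[0, "mean"] == 2.0 and table.loc[0, "sd"] == 1.0

    def test_idempotent(self):
        once, _ = standardize(_long([3.0, 1.0, 5.0, 2.0]))
        twice, _ = standardize(once)
        np.testing.assert_allclose(
            once["value"].to_numpy(), twice["value"].to_numpy(), atol=1e-12
        )

    def test_constant_biomarker_excluded_with_warning(self):
        cohort = pd.concat(
            [_long([5.0, 5.0, 5.0], "const"), _long([1.0, 2.0, 3.0], "ok")]
        )
        with pytest.warns(UserWarning, match="const"):
            out, table = standardize(cohort)
        assert set(out["biomarker_id"]) == {"ok"}


class TestDesign:
    def test_sixteen_columns_ten_interactions(self):
        cov = make_covariates(20, 2)
        X = design_matrix(cov)
        assert X.shape[1] == 16
        assert len(INTERACTIONS) == 10

    def test_interaction_is_elementwise_product(self):
        cov = make_covariates(10, 2)
        X = design_matrix(cov)
        j = DESIGN_COLUMNS.index("age:ds")
        np.testing.assert_allclose(
            X[:, j], cov["age"].to_numpy() * cov["ds"].to_numpy()
        )

    def test_missing_covariate_named(self):
        cov = make_covariates(10, 2).drop(columns=["apoe4"])
        with pytest.raises(ValueError, match="apoe4"):
            design_matrix(cov)


class TestRobustFit:
    def test_noiseless_exact_recovery(self):
        cov = make_covariates(50, 3, seed=1)
        X = design_matrix(cov)
        rng = np.random.default_rng(1)
        beta = rng.normal(size=16)
        fit = fit_fixed_robust(X, X @ beta)
        np.testing.assert_allclose(fit.beta.to_numpy(), beta, atol=1e-8)

    def test_resists_gross_outliers_where_ols_does_not(self):
        cov = make_covariates(500, 1, seed=2)
        X = design_matrix(cov)
        rng = np.random.default_rng(2)
        beta = np.zeros(16)
        beta[DESIGN_COLUMNS.index("ds")] = 1.0
        clean = X @ beta + rng.normal(0, 1, len(X))
        fit_clean = fit_fixed_robust(X, clean)
        clean_err = np.abs(fit_clean.beta.to_numpy() - beta).max()

        y = clean.copy()
        bad = rng.choice(len(y), size=len(y) // 20, replace=False)
        y[bad] += 20.0 * rng.choice([-1, 1], size=len(bad))
        fit_rob = fit_fixed_robust(X, y)
        rob_err = np.abs(fit_rob.beta.to_numpy() - beta).max()
        ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ols_err = np.abs(ols_beta - beta).max()
        assert rob_err < 3 * clean_err
        assert ols_err > 10 * clean_err

    def test_matches_ols_when_residuals_are_negligible(self):
        # with near-zero residual scale every bisquare weight converges to 1
        cov = make_covariates(200, 2, seed=3)
        X = design_matrix(cov)
        rng = np.random.default_rng(3)
        y = X @ rng.normal(size=16) + rng.normal(0, 1e-6, len(X))
        fit = fit_fixed_robust(X, y)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta.to_numpy(), ols, atol=1e-6)

    def test_duplicated_rows_leave_estimate_unchanged(self):
        cov = make_covariates(100, 2, seed=4)
        X = design_matrix(cov)
        rng = np.random.default_rng(4)
        y = X @ rng.normal(size=16) + rng.normal(0, 1, len(X))
        fit1 = fit_fixed_robust(X, y)
        fit2 = fit_fixed_robust(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(
            fit1.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-6
        )

    def test_rank_deficient_design_reported(self):
        cov = make_covariates(50, 2)
        X = design_matrix(cov)
        X[:, 4] = X[:, 3]  # duplicate a column
        with pytest.raises(ValueError, match="rank deficient"):
            fit_fixed_robust(X, np.zeros(len(X)))


def _mixed_data(n_sub=500, n_vis=4, sd0=1.0, sd1=0.0, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    sub = np.repeat(np.arange(n_sub), n_vis)
    age = rng.uniform(40, 70, n_sub)[sub] + np.tile(np.arange(n_vis), n_sub)
    ds = rng.integers(1, 5, n_sub)[sub].astype(float)
    X = np.column_stack([np.ones_like(age), age, ds])
    y = X @ np.array([0.0, 0.02, 0.5]) + rng.normal(0, noise, len(age))
    y += sd0 * rng.normal(0, 1, n_sub)[sub]
    y += sd1 * rng.normal(0, 1, n_sub)[sub] * age
    return X, y, sub, age


NAMES3 = ["intercept", "age", "ds"]


class TestMixedFit:
    def test_variance_recovery_random_intercept(self):
        X, y, sub, _ = _mixed_data(sd0=1.0, noise=1.0, seed=10)
        fit = fit_mixed(X, y, sub, random="intercept", names=NAMES3)
        assert fit.random_sd[0] == pytest.approx(1.0, rel=0.15)
        assert fit.residual_sd == pytest.approx(1.0, rel=0.15)

    def test_boundary_zero_variance_recovered(self):
        X, y, sub, _ = _mixed_data(sd0=0.0, noise=1.0, seed=11)
        fit = fit_mixed(X, y, sub, random="intercept", names=NAMES3)
        assert fit.random_sd[0] ** 2 <= 1e-3
        assert any("boundary" in w for w in fit.warnings)

    def test_agrees_with_statsmodels_mixedlm(self):
        # independent oracle on a well-conditioned random-intercept problem
        X, y, sub, _ = _mixed_data(n_sub=150, sd0=1.0, seed=12)
        fit = fit_mixed(X, y, sub, random="intercept", names=NAMES3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(
                y, X, groups=sub, exog_re=np.ones((len(y), 1))
            ).fit(reml=False)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-3)
        np.testing.assert_allclose(fit.beta.to_numpy(), ref.fe_params, atol=1e-4)
        assert fit.random_sd[0] == pytest.approx(
            np.sqrt(ref.cov_re[0, 0]), abs=1e-3
        )

    def test_random_slope_recovery(self):
        # a strong, well-identified slope component (sd 0.5/year)
        X, y, sub, age = _mixed_data(sd0=1.0, sd1=0.5, seed=13)
        fit = fit_mixed(X, y, sub, age=age, random="intercept_slope",
                        names=NAMES3)
        assert fit.random_sd[1] == pytest.approx(0.5, rel=0.15)

    def test_single_visit_returns_with_warning(self):
        X, y, sub, _ = _mixed_data(n_sub=300, n_vis=1, sd0=0.5, seed=14)
        fit = fit_mixed(X, y, sub, random="intercept", names=NAMES3)
        assert any("single visit" in w for w in fit.warnings)


class TestBICSelection:
    def _stub(self, variant, ll, k, n=100):
        return FittedBiomarkerModel(
            biomarker_id="m", variant=variant,
            beta=pd.Series(np.zeros(3), index=NAMES3), random_sd=None,
            residual_sd=1.0, log_likelihood=ll,
            bic=k * np.log(n) - 2 * ll, n_obs=n, n_params=k,
        )

    def test_equal_loglik_prefers_fewest_parameters(self):
        a = self._stub("fixed_robust", -50.0, 17)
        b = self._stub("mixed_intercept", -50.0, 18)
        assert select_model_bic([a, b]).variant == "fixed_robust"

    def test_mismatched_n_obs_rejected(self):
        a = self._stub("fixed_robust", -50.0, 17, n=100)
        b = self._stub("mixed_intercept", -40.0, 18, n=120)
        with pytest.raises(ValueError, match="n_obs"):
            select_model_bic([a, b])

    def test_selected_bic_is_minimal(self):
        X, y, sub, age = _mixed_data(sd0=1.0, seed=15)
        fits = [
            fit_fixed_robust(X, y, NAMES3),
            fit_mixed(X, y, sub, random="intercept", names=NAMES3),
            fit_mixed(X, y, sub, age=age, random="intercept_slope",
                      names=NAMES3),
        ]
        best = select_model_bic(fits)
        assert best.bic == min(f.bic for f in fits)
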