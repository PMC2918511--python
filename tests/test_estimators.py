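"""Model fitting: separable MLEs, proportional joint fits, PMLEs, tuning."""

import json

import numpy as np
import pandas as pd
import pytest

import twopartcac as tp
from twopartcac.estimators import TwoPartModel, select_tuning
from twopartcac.exceptions import DegenerateModelError, DesignError


def _xy(cohort, spec="i.1"):
    spec = tp.load_spec(spec)
    return cohort[spec.covariates], cohort["cac"].to_numpy()


class TestNonproportionalParametric:
    def test_matches_separate_logistic_and_ols_fits(self, cohort_ii1):
        # oracle: statsmodels IRLS logistic + closed-form least squares
        import statsmodels.api as sm

        m = tp.fit_nonproportional_parametric("ii.1", cohort_ii1)
        X, _ = _xy(cohort_ii1, "ii.1")
        Xd = sm.add_constant(X.to_numpy())
        z = cohort_ii1["z"].to_numpy()
        logit = sm.Logit(z, Xd).fit(disp=0)
        np.testing.assert_allclose(
            np.r_[m.params_.a0, m.params_.theta1], logit.params, atol=1e-6
        )
        ols = sm.OLS(cohort_ii1.loc[z == 1, "t"], Xd[z == 1]).fit()
        np.testing.assert_allclose(
            np.r_[m.params_.b0, m.params_.theta2], ols.params, atol=1e-6
        )
        # sigma is the MLE (n1 denominator), not the unbiased variant
        assert m.sigma_**2 == pytest.approx(float((ols.resid**2).sum()) / (z == 1).sum())

    def test_all_nonzero_cohort_rejected(self, cohort_ii1):
        coh = cohort_ii1.copy()
        coh["cac"] = coh["cac"] + 1.0  # no zeros left
        with pytest.raises(DegenerateModelError):
            tp.fit("ii.1", coh)

    def test_intercepts_recovered_within_analytic_se(self, config):
        spec = tp.ModelSpec("intercept_only", False, {})
        a0, b0, sigma = 0.4, 4.0, 1.2
        truth = tp.TrueModel(spec=spec, a0=a0, b0=b0, sigma=sigma, coef={}, coef2={})
        n = 5000
        coh = tp.generate_cohort(truth, n, seed=31, config=config)
        m = tp.fit(spec, coh)
        p = 1 / (1 + np.exp(-a0))
        se_a0 = 1 / np.sqrt(n * p * (1 - p))
        se_b0 = sigma / np.sqrt(n * p)
        assert abs(m.params_.a0 - a0) < 4 * se_a0
        assert abs(m.params_.b0 - b0) < 4 * se_b0

    def test_complete_separation_aborts_with_diagnostic(self):
        rng = np.random.default_rng(33)
        x = rng.normal(size=300)
        X = pd.DataFrame({"x": x})
        y = np.where(x > 0, np.exp(4.0 + rng.normal(0, 0.5, 300)), 0.0)
        spec = tp.ModelSpec("toy", False, {"x": "linear"})
        with pytest.raises(DegenerateModelError, match="separation"):
            TwoPartModel(spec=spec).fit(X, y)


class TestProportionalParametric:
    def test_constrained_loglik_below_unconstrained(self, fitted_i1, fitted_ii1,
                                                    cohort_i1):
        m_free = tp.fit("ii.1", cohort_i1)
        assert fitted_i1.loglik_ <= m_free.loglik_ + 1e-8

    def test_tau_recovery(self, config):
        truth = tp.example_truth("i.1", tau=0.67)
        coh = tp.generate_cohort(truth, 20_000, seed=37, config=config)
        m = tp.fit("i.1", coh)
        assert abs(m.tau_ - 0.67) < 0.05

    def test_anchor_swap_inverts_tau(self, cohort_i1, fitted_i1):
        m_swap = tp.fit_proportional_parametric("i.1", cohort_i1, anchor="continuous")
        assert m_swap.tau_ * fitted_i1.tau_ == pytest.approx(1.0, abs=1e-4)
        # same model, same likelihood
        assert m_swap.loglik_ == pytest.approx(fitted_i1.loglik_, abs=1e-6)

    def test_zero_effect_truth_flags_degenerate_tau(self, config):
        spec = tp.load_spec("i.1")
        truth = tp.TrueModel(spec=spec, a0=0.0, b0=4.0, sigma=1.0,
                             coef={c: 0.0 for c in spec.covariates}, tau=0.67)
        coh = tp.generate_cohort(truth, 2000, seed=41, config=config)
        with pytest.warns(RuntimeWarning, match="tau"):
            m = tp.fit("i.1", coh)
        assert m.convergence_["hessian_degenerate"]

    def test_intercept_only_proportional_rejected(self, cohort_i1):
        spec = tp.ModelSpec("prop_empty", True, {})
        X = cohort_i1[["age"]]
        with pytest.raises(DegenerateModelError):
            TwoPartModel(spec=spec).fit(X, cohort_i1["cac"].to_numpy())


class TestSemiparametric:
    def test_affine_basis_collapse_equals_parametric_fit(self, cohort_i1):
        # q=2, degree-1 splines span exactly the affine functions, so at
        # lambda=0 the PMLE coincides with the all-linear parametric MLE
        spec = tp.load_spec("iv").with_basis(basis_dim=2, degree=1)
        m_semi = TwoPartModel(spec=spec, lam=0.0).fit(*_xy(cohort_i1, "iv"))
        m_param = tp.fit("ii.1", cohort_i1)
        assert m_semi.loglik_ == pytest.approx(m_param.loglik_, abs=1e-6)

    def test_fitted_smooths_mean_centered(self, cohort_i1):
        m = tp.fit("iv", cohort_i1, lam=1e-2)
        for cov in m.design_.bases:
            x = cohort_i1[cov].to_numpy()
            basis = m.design_.bases[cov]
            sl = m.design_.spline_slices[cov]
            vals = basis.evaluate_centered(x) @ m.params_.theta1[sl]
            assert abs(vals.mean()) < 1e-10

    def test_proportional_semiparametric_fit_converges(self, cohort_i1):
        m = tp.fit("iii", cohort_i1, lam=1e-2)
        assert m.convergence_["status"] == "converged"
        assert m.convergence_["sup_gradient"] < 1e-4

    def test_gradient_stationarity_all_specs(self, cohort_i1):
        # numerical sup-gradient of the per-observation criterion < 1e-4
        for name in tp.PRESET_NAMES:
            lam = 1e-2 if tp.load_spec(name).family == "semiparametric" else None
            m = tp.fit(name, cohort_i1, lam=lam)
            assert m.convergence_["sup_gradient"] < 1e-4, name


class TestTuningSelection:
    def test_single_value_grid_returned(self, cohort_i1):
        X, y = _xy(cohort_i1, "iv")
        assert select_tuning("iv", X, y, grid=[0.5], folds=3) == 0.5

    def test_duplicate_grid_values_deduplicated(self, cohort_i1):
        X, y = _xy(cohort_i1.iloc[:800], "iv")
        lam = select_tuning("iv", X, y, grid=[0.1, 0.1, 0.1, 10.0, 10.0], folds=3)
        assert lam in (0.1, 10.0)

    def test_empty_grid_rejected(self, cohort_i1):
        X, y = _xy(cohort_i1, "iv")
        with pytest.raises(DesignError):
            select_tuning("iv", X, y, grid=[], folds=3)

    def test_linear_truth_prefers_smoother_fits(self, config):
        # under an (affine-smooth) truth the held-out likelihood favors
        # heavy smoothing: the top grid value should win most of the time
        truth = tp.example_truth("iv")  # age/bmi/hdl affine, ldl mildly curved
        grid = [1e-3, 1e-1, 1e1]
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            coh = tp.generate_cohort(truth, 600, seed=1000 + seed, config=config)
            X, y = _xy(coh, "iv")
            lam = select_tuning("iv", X, y, grid=grid, folds=3, seed=seed)
            wins += lam >= grid[1]
        assert wins >= 0.8 * n_seeds


class TestDispatcher:
    def test_routes_by_spec(self, cohort_i1):
        m = tp.fit("i.1", cohort_i1)
        assert m.params_.proportional and m.lambda_ is None
        m = tp.fit("ii.2", cohort_i1)
        assert not m.params_.proportional

    def test_semiparametric_auto_tuning_recorded(self, cohort_i1):
        m = tp.fit("iv", cohort_i1.iloc[:600], lam=None,
                   lambda_grid=[1e-2, 1e0], cv=3)
        assert m.tuned_ and m.lambda_ in (1e-2, 1e0)

    def test_identical_inputs_identical_serialization(self, cohort_i1):
        a = tp.fit("i.2", cohort_i1).to_dict()
        b = tp.fit("i.2", cohort_i1).to_dict()
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_missing_response_column_rejected(self, cohort_i1):
        with pytest.raises(DesignError):
            tp.fit("i.1", cohort_i1.drop(columns=["cac"]))


class TestEstimatorProtocol:
    def test_get_set_params_roundtrip(self):
        m = TwoPartModel(spec="i.2", lam=0.5, cv=3)
        params = m.get_params()
        assert params["spec"] == "i.2" and params["lam"] == 0.5
        m2 = TwoPartModel().set_params(**params)
        assert m2.lam == 0.5 and m2.cv == 3

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        m = TwoPartModel(spec="iii", lam=0.1, anchor="continuous")
        c = clone(m)
        assert c.lam == 0.1 and c.anchor == "continuous"

    def test_predict_proba_shape_and_range(self, fitted_ii1, cohort_ii1):
        X, _ = _xy(cohort_ii1.iloc[:20], "ii.1")
        proba = fitted_ii1.predict_proba(X)
        assert proba.shape == (20, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_score_is_mean_loglik(self, fitted_ii1, cohort_ii1):
        X, y = _xy(cohort_ii1, "ii.1")
        assert fitted_ii1.score(X, y) == pytest.approx(
            fitted_ii1.loglik_ / len(y), rel=1e-12
        )

    def test_unfitted_predict_raises(self, cohort_ii1):
        X, _ = _xy(cohort_ii1.iloc[:5], "ii.1")
        with pytest.raises(DesignError):
            TwoPartModel().predict(X)

    def test_negative_cac_rejected(self, cohort_ii1):
        X, y = _xy(cohort_ii1.iloc[:50].copy(), "ii.1")
        y = y.copy()
        y[7] = -1.0
        with pytest.raises(DesignError):
            TwoPartModel().fit(X, y)
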