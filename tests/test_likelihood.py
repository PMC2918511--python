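"""Design construction and the two-part log-likelihood."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import twopartcac as tp
from twopartcac.likelihood import (
    Design,
    TwoPartParams,
    linear_predictors,
    log_likelihood,
    penalized_log_likelihood,
    roughness_penalty,
)


def _random_params(design, rng, proportional=False, scale=None):
    # per-column scaling keeps the linear predictors in a moderate range
    # (raw mmHg/mg-dL covariate scales would saturate the logistic link)
    s = np.ones(design.p) if scale is None else scale
    kw = dict(a0=rng.normal(), b0=rng.normal(),
              theta1=rng.normal(0, 0.3, design.p) * s,
              sigma=float(np.exp(rng.normal(0, 0.3))))
    if proportional:
        kw["tau"] = float(rng.normal(0.7, 0.3))
    else:
        kw["theta2"] = rng.normal(0, 0.3, design.p) * s
    return TwoPartParams(**kw)


def _column_scale(design, cohort):
    M = design.matrix(cohort)
    return 1.0 / (M.std(axis=0) + 1.0)


class TestBuildDesign:
    def test_linear_spec_column_count(self, cohort_i1):
        d = tp.build_design(tp.load_spec("i.1"), cohort_i1)
        assert d.p == 13
        assert not d.bases

    def test_quadratic_spec_adds_two_columns(self, cohort_i1):
        d = tp.build_design(tp.load_spec("i.2"), cohort_i1)
        assert d.p == 15
        assert "ldl^2" in d.labels and "hdl^2" in d.labels

    def test_semiparametric_spec_blocks(self, cohort_i1):
        d = tp.build_design(tp.load_spec("iv"), cohort_i1)
        assert len(d.spline_slices) == 4  # age, bmi, ldl, hdl
        n_param = sum(1 for l in d.labels if ":s" not in l)
        assert n_param == 9  # 7 binary + sbp + dbp

    def test_unknown_covariate_rejected(self, cohort_i1):
        spec = tp.ModelSpec("bad", False, {"ghost": "linear"})
        with pytest.raises(tp.DesignError):
            tp.build_design(spec, cohort_i1)


class TestLinearPredictors:
    def test_zero_coefficients_give_intercepts(self, cohort_i1):
        d = tp.build_design(tp.load_spec("ii.1"), cohort_i1)
        params = TwoPartParams(a0=1.5, b0=-0.5, theta1=np.zeros(13),
                               theta2=np.zeros(13), sigma=1.0)
        eta1, eta2 = linear_predictors(params, d, cohort_i1)
        assert np.all(eta1 == 1.5) and np.all(eta2 == -0.5)

    def test_unit_tau_equal_intercepts_identity(self, cohort_i1):
        d = tp.build_design(tp.load_spec("i.1"), cohort_i1)
        rng = np.random.default_rng(5)
        params = TwoPartParams(a0=0.3, b0=0.3, theta1=rng.normal(0, 0.2, 13),
                               tau=1.0, sigma=1.0)
        eta1, eta2 = linear_predictors(params, d, cohort_i1)
        np.testing.assert_allclose(eta1, eta2, atol=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_proportionality_identity_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        coh = tp.generate_cohort(tp.example_truth("i.1"), 50, seed=seed % 97)
        d = tp.build_design(tp.load_spec("i.1"), coh)
        params = _random_params(d, rng, proportional=True)
        eta1, eta2 = linear_predictors(params, d, coh)
        resid = (eta2 - params.b0) - params.tau * (eta1 - params.a0)
        assert np.max(np.abs(resid)) < 1e-12


class TestLogLikelihood:
    def test_single_zero_subject_flat_logistic(self):
        spec = tp.ModelSpec("int", False, {})
        coh = pd.DataFrame({"t": [0.0], "z": [0]})
        d = Design(spec=spec, labels=[])
        params = TwoPartParams(a0=0.0, b0=0.0, theta1=np.zeros(0),
                               theta2=np.zeros(0), sigma=1.0)
        assert log_likelihood(params, d, coh, M=np.zeros((1, 0))) == pytest.approx(
            np.log(0.5)
        )

    def test_single_positive_subject_zero_residual(self):
        spec = tp.ModelSpec("int", False, {})
        coh = pd.DataFrame({"t": [2.0], "z": [1]})
        d = Design(spec=spec, labels=[])
        params = TwoPartParams(a0=0.0, b0=2.0, theta1=np.zeros(0),
                               theta2=np.zeros(0), sigma=1.0)
        expected = np.log(0.5) - 0.5 * np.log(2 * np.pi)  # ~ -1.612
        val = log_likelihood(params, d, coh, M=np.zeros((1, 0)))
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(-1.612, abs=5e-4)

    def test_matches_bruteforce_bernoulli_plus_normal(self, cohort_ii1):
        # independent oracle: per-subject Bernoulli log-pmf + Normal log-pdf
        coh = cohort_ii1.iloc[:100]
        d = tp.build_design(tp.load_spec("ii.1"), coh)
        rng = np.random.default_rng(9)
        params = _random_params(d, rng, scale=_column_scale(d, coh))
        eta1, eta2 = linear_predictors(params, d, coh)
        p = 1 / (1 + np.exp(-eta1))
        z = coh["z"].to_numpy()
        t = coh["t"].to_numpy()
        oracle = sum(
            np.log(p[i]) + norm.logpdf(t[i], eta2[i], params.sigma)
            if z[i] == 1 else np.log(1 - p[i])
            for i in range(len(coh))
        )
        mine = log_likelihood(params, d, coh)
        assert mine == pytest.approx(oracle, abs=1e-10 * abs(oracle))

    def test_decomposes_into_part_likelihoods(self, cohort_ii1):
        from twopartcac.likelihood import bernoulli_loglik, normal_loglik

        d = tp.build_design(tp.load_spec("ii.1"), cohort_ii1)
        params = _random_params(d, np.random.default_rng(11),
                                scale=_column_scale(d, cohort_ii1))
        eta1, eta2 = linear_predictors(params, d, cohort_ii1)
        z = cohort_ii1["z"].to_numpy()
        t = cohort_ii1["t"].to_numpy()
        total = log_likelihood(params, d, cohort_ii1)
        assert total == pytest.approx(
            bernoulli_loglik(eta1, z) + normal_loglik(eta2, t, z, params.sigma),
            rel=1e-12,
        )

    def test_extreme_predictors_stay_finite(self, cohort_ii1):
        d = tp.build_design(tp.load_spec("ii.1"), cohort_ii1)
        params = TwoPartParams(a0=500.0, b0=4.0, theta1=np.zeros(13),
                               theta2=np.zeros(13), sigma=1.0)
        assert np.isfinite(log_likelihood(params, d, cohort_ii1))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            TwoPartParams(a0=0, b0=0, theta1=np.zeros(1), theta2=np.zeros(1), sigma=0.0)


class TestPenalizedLogLikelihood:
    def test_zero_lambda_equals_scaled_loglik(self, cohort_i1):
        d = tp.build_design(tp.load_spec("iv"), cohort_i1)
        params = _random_params(d, np.random.default_rng(13))
        n = len(cohort_i1)
        assert penalized_log_likelihood(params, d, cohort_i1, 0.0) == pytest.approx(
            log_likelihood(params, d, cohort_i1) / n, rel=1e-12
        )

    def test_affine_smooths_incur_no_penalty(self, cohort_i1):
        d = tp.build_design(tp.load_spec("iv"), cohort_i1)
        theta = np.zeros(d.p)
        for cov, sl in d.spline_slices.items():
            theta[sl] = d.bases[cov].affine_coefs(0.3)
        params = TwoPartParams(a0=0, b0=4, theta1=theta, theta2=theta.copy(), sigma=1.0)
        assert roughness_penalty(params, d) < 1e-8

    def test_penalty_counts_both_parts_when_nonproportional(self, cohort_i1):
        d = tp.build_design(tp.load_spec("iv"), cohort_i1)
        rng = np.random.default_rng(17)
        th1, th2 = rng.normal(0, 0.2, d.p), rng.normal(0, 0.2, d.p)
        both = TwoPartParams(a0=0, b0=0, theta1=th1, theta2=th2, sigma=1.0)
        prop = TwoPartParams(a0=0, b0=0, theta1=th1, tau=1.0, sigma=1.0)
        assert roughness_penalty(both, d) == pytest.approx(
            d.roughness(th1) + d.roughness(th2), rel=1e-12
        )
        assert roughness_penalty(prop, d) == pytest.approx(d.roughness(th1), rel=1e-12)

    def test_negative_lambda_rejected(self, cohort_i1):
        d = tp.build_design(tp.load_spec("i.1"), cohort_i1)
        params = _random_params(d, np.random.default_rng(19))
        with pytest.raises(ValueError):
            penalized_log_likelihood(params, d, cohort_i1, -0.1)

    def test_penalty_equals_quadrature_of_fitted_curvature(self, cohort_i1):
        # quadrature oracle on the fitted smooth's second derivative
        d = tp.build_design(tp.load_spec("iv"), cohort_i1)
        rng = np.random.default_rng(23)
        theta = rng.normal(0, 0.5, d.p)
        total = 0.0
        for cov, sl in d.spline_slices.items():
            b = d.bases[cov]
            grid = np.linspace(b.lower, b.upper, 20001)
            d2 = (b.evaluate(grid, nu=2) @ b.constraint_map) @ theta[sl]
            total += np.trapezoid(d2 * d2, grid)
        assert d.roughness(theta) == pytest.approx(total, rel=1e-5)
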