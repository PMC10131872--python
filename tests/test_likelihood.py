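"""MTP likelihood machinery: elementary quantities, the integrated subject
likelihood against independent oracles, and exact gradients."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats
from scipy.special import expit

import mtpcost as m
from mtpcost.likelihood import (
    LikelihoodError,
    MTPParams,
    PanelEvaluator,
    QuadratureSpec,
    standard_nodes,
)


def _params(p=2, **kw):
    defaults = dict(alpha=np.zeros(p), beta=np.zeros(p), kappa=1.0,
                    sigma_a=0.5, sigma_d=0.5, rho=0.3)
    defaults.update(kw)
    return MTPParams(**defaults)


def _random_subject(rng, n_obs=3):
    """A small random subject with a mix of zero and positive costs."""
    x1 = np.column_stack([np.ones(n_obs), rng.normal(0, 1, n_obs)])
    y = np.where(rng.random(n_obs) < 0.4, 0.0, rng.gamma(1.0, 50.0, n_obs))
    return x1, x1.copy(), y


class TestZeroProb:
    def test_symmetry_at_zero(self):
        assert m.zero_prob([1.0], [0.0]) == 0.5

    def test_reference_intercept(self):
        # logistic evaluated at the reference binary intercept
        assert m.zero_prob([1.0], [-0.4169]) == pytest.approx(0.3973, abs=5e-5)

    def test_monotone_in_random_effect(self):
        vals = [m.zero_prob([1.0, 2.0], [0.1, -0.2], a) for a in (-1, 0, 1, 2)]
        assert np.all(np.diff(vals) > 0)


class TestMarginalMean:
    def test_identity(self):
        assert m.marginal_mean([1.0], [0.0]) == 1.0

    def test_reference_intercept(self):
        # exp of the reference mean intercept, ~7.24e4 (log-KRW scale)
        assert m.marginal_mean([1.0], [11.1894]) == pytest.approx(7.24e4, rel=2e-3)

    def test_coefficient_is_log_cost_ratio(self):
        beta = [1.0, 0.3]
        ratio = m.marginal_mean([1.0, 2.0], beta) / m.marginal_mean([1.0, 1.0], beta)
        assert ratio == pytest.approx(np.exp(0.3))

    def test_overflow_raises(self):
        with pytest.raises(LikelihoodError, match="overflow"):
            m.marginal_mean([1.0], [800.0])


class TestConditionalPositiveMean:
    def test_ratio_definition(self):
        assert m.conditional_positive_mean(100.0, 0.5) == 200.0

    def test_no_zeros_limit(self):
        assert m.conditional_positive_mean(42.0, 1.0) == 42.0

    @given(st.floats(min_value=1e-3, max_value=1e6),
           st.floats(min_value=1e-4, max_value=1.0))
    def test_pi_mu_identity(self, nu, pi):
        mu = m.conditional_positive_mean(nu, pi)
        assert pi * mu == pytest.approx(nu, rel=1e-12)
        assert mu >= nu

    def test_floor_clip(self):
        assert m.conditional_positive_mean(1.0, 0.0) == 1e6


class TestGammaLogpdf:
    @pytest.mark.parametrize("y,kappa,mu", [
        (1.0, 0.8, 2.0), (50.0, 2.5, 30.0), (0.01, 1.0, 1.0),
    ])
    def test_matches_scipy(self, y, kappa, mu):
        expected = stats.gamma.logpdf(y, a=kappa, scale=mu / kappa)
        assert m.gamma_logpdf(y, kappa, mu) == pytest.approx(expected, rel=1e-12)

    def test_exponential_special_case(self):
        # kappa = 1: density (1/mu) exp(-y/mu)
        assert m.gamma_logpdf(3.0, 1.0, 10.0) == pytest.approx(
            -np.log(10.0) - 0.3, rel=1e-12)

    def test_density_integrates_to_one(self):
        val, _ = integrate.quad(lambda y: np.exp(m.gamma_logpdf(y, 0.8, 5.0)),
                                0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_mean(self, rng):
        mu, kappa, n = 7.0, 0.8, 1_000_000
        draws = rng.gamma(shape=kappa, scale=mu / kappa, size=n)
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - mu) < 3 * se

    def test_domain_errors(self):
        with pytest.raises(LikelihoodError):
            m.gamma_logpdf(0.0, 1.0, 1.0)
        with pytest.raises(LikelihoodError):
            m.gamma_logpdf(1.0, -1.0, 1.0)


class TestSubjectLoglik:
    def test_degenerate_equals_independent_two_part(self, rng):
        x1, x2, y = _random_subject(rng, 5)
        params = _params(sigma_a=0.0, sigma_d=0.0, rho=0.0,
                         alpha=[0.2, -0.4], beta=[3.0, 0.1], kappa=0.7)
        got = m.subject_loglik(x1, x2, y, params)
        # independent oracle assembled directly from scipy densities
        pi = expit(x1 @ np.asarray(params.alpha))
        expected = 0.0
        for j in range(len(y)):
            if y[j] > 0:
                mu = np.exp(x2[j] @ np.asarray(params.beta)) / pi[j]
                expected += np.log(pi[j]) + stats.gamma.logpdf(
                    y[j], a=params.kappa, scale=mu / params.kappa)
            else:
                expected += np.log1p(-pi[j])
        assert got == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_monte_carlo_oracle(self, rng):
        params = _params(alpha=[0.3, 0.5], beta=[3.5, -0.2], kappa=0.9,
                         sigma_a=0.6, sigma_d=0.5, rho=0.4)
        for _ in range(3):
            x1, x2, y = _random_subject(rng)
            llq = m.subject_loglik(x1, x2, y, params, QuadratureSpec(15))
            llmc, se = m.subject_loglik_mc(x1, x2, y, params, 100_000, rng)
            assert abs(llq - llmc) < 3 * se

    def test_single_zero_obs_against_1d_quadrature(self):
        # one y = 0 observation, intercept only: the d-dimension integrates
        # out, leaving a 1-D logistic-normal integral
        alpha1, sigma_a = -0.4169, 0.8
        params = _params(p=1, alpha=[alpha1], beta=[3.0],
                         sigma_a=sigma_a, sigma_d=0.6, rho=0.5)
        got = m.subject_loglik([[1.0]], [[1.0]], [0.0], params, QuadratureSpec(21))
        val, _ = integrate.quad(
            lambda a: (1 - expit(alpha1 + a)) * stats.norm.pdf(a, 0, sigma_a),
            -10, 10)
        assert got == pytest.approx(np.log(val), abs=1e-8)

    def test_all_zero_subject_factorizes_when_rho_zero(self):
        # with rho = 0 and no positive costs the integrand involves only
        # the binary-part intercept, so 2-D quadrature equals the 1-D result
        params = _params(p=1, alpha=[0.3], beta=[2.0],
                         sigma_a=0.7, sigma_d=0.9, rho=0.0)
        y = [0.0, 0.0, 0.0]
        x = [[1.0]] * 3
        got = m.subject_loglik(x, x, y, params, QuadratureSpec(25, adaptive=False))
        z, w = np.polynomial.hermite_e.hermegauss(25)
        w = w / np.sqrt(2 * np.pi)
        vals = np.prod([1 - expit(0.3 + params.sigma_a * z)] * 3, axis=0)
        assert got == pytest.approx(np.log(np.sum(w * vals)), abs=1e-8)

    def test_empty_subject_raises(self):
        with pytest.raises(LikelihoodError):
            m.subject_loglik(np.empty((0, 1)), np.empty((0, 1)), [], _params(p=1))

    def test_non_finite_integrand_names_subject(self):
        params = _params(p=1, alpha=[0.0], beta=[-500.0], kappa=1.0)
        with pytest.raises(LikelihoodError, match="subject"):
            m.subject_loglik([[1.0]], [[1.0]], [1e300], params)


class TestTotalLoglik:
    def test_singleton_panel_equals_subject(self, rng):
        x1, x2, y = _random_subject(rng, 4)
        params = _params(alpha=[0.1, 0.2], beta=[3.0, 0.0])
        import pandas as pd
        panel = pd.DataFrame({
            "subject_id": ["s"] * 4, "time": range(4), "cost": y,
            "region": "nonvulnerable", "age": x1[:, 1] * 0, "sex": "male",
            "cci": 0,
        })
        dm = m.build_design(panel, covariate_spec=())
        p8 = _params(p=8, alpha=np.r_[0.1, np.zeros(7)],
                     beta=np.r_[3.0, np.zeros(7)])
        assert m.total_loglik(dm, p8) == pytest.approx(
            m.subject_loglik(dm.x1, dm.x2, dm.y, p8), rel=1e-12)

    def test_subject_order_invariance(self, small_panel, small_config):
        params = small_config.params()
        dm1 = m.build_design(small_panel)
        shuffled = small_panel.sample(frac=1.0, random_state=1)
        dm2 = m.build_design(shuffled)
        ll1 = m.total_loglik(dm1, params, QuadratureSpec(5))
        ll2 = m.total_loglik(dm2, params, QuadratureSpec(5))
        assert ll1 == pytest.approx(ll2, rel=1e-10)

    def test_doubling_panel_doubles_loglik(self, small_panel, small_config):
        import pandas as pd
        params = small_config.params()
        dm1 = m.build_design(small_panel)
        dup = small_panel.copy()
        dup["subject_id"] = dup["subject_id"] + "_copy"
        dm2 = m.build_design(pd.concat([small_panel, dup]))
        ll1 = m.total_loglik(dm1, params, QuadratureSpec(5))
        ll2 = m.total_loglik(dm2, params, QuadratureSpec(5))
        assert ll2 == pytest.approx(2 * ll1, rel=1e-10)

    def test_adaptive_node_convergence_shrinks(self, small_design, small_config):
        params = small_config.params()
        lls = [m.total_loglik(small_design, params, QuadratureSpec(k))
               for k in (5, 9, 15)]
        d1, d2 = abs(lls[1] - lls[0]), abs(lls[2] - lls[1])
        assert d2 < d1


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, small_design,
                                                          small_config):
        params = small_config.params()
        ev = PanelEvaluator(small_design)
        nodes = ev.adaptive_nodes(params, 3)
        theta = params.to_internal()
        _, g = ev.loglik_and_grad(theta, nodes)
        for k in range(0, len(theta), 5):
            h = 1e-6 * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (ev.loglik(MTPParams.from_internal(tp, ev.p), nodes)
                  - ev.loglik(MTPParams.from_internal(tm, ev.p), nodes)) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=5e-6, abs=1e-6)

    def test_subject_gradients_sum_to_total(self, small_design, small_config):
        params = small_config.params()
        ev = PanelEvaluator(small_design)
        nodes = ev.adaptive_nodes(params, 3)
        theta = params.to_internal()
        _, g = ev.loglik_and_grad(theta, nodes)
        G = ev.subject_gradients(theta, nodes)
        np.testing.assert_allclose(G.sum(axis=0), g, rtol=1e-8, atol=1e-8)


class TestInternalParameterization:
    def test_round_trip(self):
        p = _params(alpha=[0.1, -0.2], beta=[1.0, 2.0], kappa=0.8,
                    sigma_a=0.3, sigma_d=0.7, rho=0.5)
        back = MTPParams.from_internal(p.to_internal(), 2)
        assert back.kappa == pytest.approx(p.kappa, rel=1e-12)
        assert back.rho == pytest.approx(p.rho, rel=1e-12)
        np.testing.assert_allclose(back.alpha, p.alpha)

    def test_dict_round_trip(self):
        cols = ["a", "b"]
        p = _params(alpha=[0.1, -0.2], beta=[1.0, 2.0])
        back = MTPParams.from_dict(p.to_dict(cols), cols)
        np.testing.assert_allclose(back.beta, p.beta)

    @pytest.mark.parametrize("kw", [
        {"kappa": 0.0}, {"sigma_a": -1.0}, {"rho": 1.0},
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(LikelihoodError):
            _params(**kw)
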