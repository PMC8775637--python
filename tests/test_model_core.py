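"""Likelihood, posterior and conditional-update contracts of the sampler."""

import math

import numpy as np
import pytest
from scipy.stats import invgamma, norm

import lanelogit as ll
from lanelogit.model import (
    DICResult,
    gibbs_update_mu,
    gibbs_update_sigma,
    metropolis_update_beta,
    mu_conditional,
    sigma_conditional,
)


class TestLogLikelihood:
    def test_zero_coefficients_give_n_log_half(self, toy_design):
        y = np.array([1, 0, 1])
        assert ll.log_likelihood(np.zeros(2), toy_design, y) == pytest.approx(3 * math.log(0.5))

    def test_single_observation_closed_form(self):
        dm = ll.DesignMatrix(X=np.array([[1.0, 1.0]]), columns=["intercept", "x:1 vs 0"],
                             column_info={"x:1 vs 0": ("x", "1", "0")})
        val = ll.log_likelihood(np.array([1.0, 1.0]), dm, np.array([1]))
        assert val == pytest.approx(math.log(1 / (1 + math.exp(-2.0))), abs=1e-12)
        assert val == pytest.approx(math.log(0.880797), abs=1e-6)

    def test_matches_naive_probability_product(self):
        """Random n=5, k=2 instance against a direct product of Bernoulli
        probabilities computed with scipy's expit."""
        from scipy.special import expit

        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(5), rng.integers(0, 2, 5).astype(float)])
        dm = ll.DesignMatrix(X=X, columns=["intercept", "x:1 vs 0"],
                             column_info={"x:1 vs 0": ("x", "1", "0")})
        y = rng.integers(0, 2, 5)
        beta = rng.normal(size=(5, 2))
        p = expit(np.sum(beta * X, axis=1))
        expected = float(np.sum(np.log(np.where(y == 1, p, 1 - p))))
        assert ll.log_likelihood(beta, dm, y) == pytest.approx(expected, abs=1e-12)

    def test_always_nonpositive_and_rejects_nonbinary(self, toy_design):
        rng = np.random.default_rng(9)
        for _ in range(20):
            assert ll.log_likelihood(rng.normal(size=2), toy_design, np.array([1, 0, 1])) <= 0
        with pytest.raises(ValueError, match="binary"):
            ll.log_likelihood(np.zeros(2), toy_design, np.array([1, 2, 0]))


class TestLogPosterior:
    def test_prior_terms_match_scipy_densities(self, toy_design):
        """log posterior minus log likelihood equals the scipy-evaluated sum
        of the three prior products, to near machine precision."""
        rng = np.random.default_rng(10)
        y = np.array([1, 0, 1])
        prior = ll.PriorSpec(mean_loc=0.2, mean_var=3.0, var_shape=2.0, var_rate=0.5,
                             random_set=("x:1 vs 0",))
        for _ in range(10):
            mu = rng.normal(size=2)
            sigma2 = np.array([rng.gamma(2.0)])
            beta = rng.normal(size=(3, 1))
            full = np.tile(mu, (3, 1))
            full[:, 1] = beta[:, 0]
            expected = (
                ll.log_likelihood(full, toy_design, y)
                + norm.logpdf(beta[:, 0], mu[1], np.sqrt(sigma2[0])).sum()
                + norm.logpdf(mu, 0.2, np.sqrt(3.0)).sum()
                + invgamma.logpdf(sigma2[0], 2.0, scale=0.5)
            )
            got = ll.log_posterior(mu, sigma2, beta, toy_design, y, prior)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_variance_gives_minus_inf(self, toy_design):
        prior = ll.PriorSpec(random_set=("x:1 vs 0",))
        val = ll.log_posterior(np.zeros(2), np.array([0.0]), np.zeros((3, 1)),
                               toy_design, np.array([1, 0, 1]), prior)
        assert val == -np.inf

    def test_flat_prior_limit_differs_from_likelihood_by_constant(self, toy_design):
        y = np.array([1, 0, 1])
        prior = ll.PriorSpec(mean_var=1e12)
        states = [np.array([0.3, -0.2]), np.array([-1.0, 2.0]), np.array([0.0, 0.0])]
        gaps = [
            ll.log_posterior(mu, np.empty(0), None, toy_design, y, prior)
            - ll.log_likelihood(mu, toy_design, y)
            for mu in states
        ]
        assert max(gaps) - min(gaps) < 1e-9


class TestConjugateUpdates:
    def test_mu_conditional_hand_computed(self):
        """n=4 hand-set coefficients, Sigma=1, vague prior: the conditional
        collapses to (sample mean, 1/n) up to the prior's tiny contribution."""
        beta = np.array([0.2, 0.4, 0.6, 0.8])
        prior = ll.PriorSpec(mean_loc=0.0, mean_var=1e6)
        m, v = mu_conditional(beta, 1.0, prior)
        v_hand = 1.0 / (4 / 1.0 + 1e-6)
        m_hand = v_hand * (2.0 / 1.0)
        assert (m, v) == pytest.approx((m_hand, v_hand), rel=1e-12)
        assert m == pytest.approx(0.5, abs=1e-5)

    def test_flat_prior_mean_tends_to_sample_mean(self):
        beta = np.array([1.0, 3.0])
        m, _ = mu_conditional(beta, 0.7, ll.PriorSpec(mean_var=1e12))
        assert m == pytest.approx(2.0, abs=1e-9)

    def test_mu_draws_match_conditional_moments(self):
        rng = np.random.default_rng(11)
        beta = np.array([0.1, -0.3, 0.5, 0.9, -0.2])
        prior = ll.PriorSpec()
        m, v = mu_conditional(beta, 0.5, prior)
        draws = np.array([gibbs_update_mu(beta, 0.5, prior, rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(m, abs=4 * np.sqrt(v / 20_000))
        assert draws.var() == pytest.approx(v, rel=0.05)

    def test_sigma_conditional_hand_computed_rate(self):
        """Residuals (1, -1, 2, -2) about mu=0 give rate 0.001 + 5.0."""
        prior = ll.PriorSpec()
        shape, rate = sigma_conditional(np.array([1.0, -1.0, 2.0, -2.0]), 0.0, prior)
        assert shape == pytest.approx(0.001 + 2.0)
        assert rate == pytest.approx(0.001 + 5.0)

    def test_sigma_zero_spread_concentrates_at_prior_rate(self):
        """With all coefficients equal to mu the inverse-gamma mean is
        d / (c + n/2 - 1)."""
        prior = ll.PriorSpec()
        n = 1000
        beta = np.full(n, 0.7)
        shape, rate = sigma_conditional(beta, 0.7, prior)
        assert shape == pytest.approx(0.001 + n / 2)
        assert rate == pytest.approx(0.001)
        rng = np.random.default_rng(12)
        draws = np.array([gibbs_update_sigma(beta, 0.7, prior, rng) for _ in range(2_000)])
        assert draws.mean() == pytest.approx(rate / (shape - 1), rel=0.2)

    def test_sigma_draws_match_analytic_inverse_gamma_mean(self):
        rng = np.random.default_rng(13)
        beta = rng.normal(0.0, 0.8, size=50)
        prior = ll.PriorSpec(var_shape=3.0, var_rate=2.0)
        shape, rate = sigma_conditional(beta, 0.0, prior)
        draws = np.array([gibbs_update_sigma(beta, 0.0, prior, rng) for _ in range(30_000)])
        assert draws.mean() == pytest.approx(invgamma(shape, scale=rate).mean(), rel=0.02)


class TestMetropolisBeta:
    def test_zero_proposal_scale_is_stationary(self, toy_design):
        rng = np.random.default_rng(14)
        beta = np.array([0.1, 0.2, 0.3])
        eta = toy_design.X[:, 0] * 0.0 + beta * toy_design.X[:, 1]
        new, _, _ = metropolis_update_beta(
            beta, eta, toy_design.X[:, 1], np.array([1, 0, 1]), 0.0, 1.0, 0.0, rng
        )
        np.testing.assert_array_equal(new, beta)

    def test_flat_data_signal_recovers_prior(self):
        """With the design column identically zero the likelihood carries no
        information, so the chain must sample beta from N(mu, Sigma)."""
        rng = np.random.default_rng(15)
        n = 200
        mu_k, s2 = 0.4, 0.49
        beta = np.zeros(n)
        eta = np.zeros(n)
        x = np.zeros(n)
        y = np.zeros(n)
        samples = []
        for it in range(4_000):
            beta, eta, _ = metropolis_update_beta(beta, eta, x, y, mu_k, s2, 1.5, rng)
            if it >= 500:
                samples.append(beta.copy())
        draws = np.concatenate(samples)
        assert draws.mean() == pytest.approx(mu_k, abs=0.02)
        assert draws.std() == pytest.approx(np.sqrt(s2), rel=0.05)


class TestGelmanRubin:
    def _draws(self, mu):
        return ll.PosteriorDraws(
            columns=["intercept"], random_set=[], mu=mu,
            sigma2=np.zeros((mu.shape[0], mu.shape[1], 0)),
            deviance=np.zeros(mu.shape[:2]), beta_mean=np.zeros((1, 0)), n_obs=1,
        )

    def test_identical_constant_chains_report_one(self):
        mu = np.full((2, 100, 1), 1.3)
        assert ll.gelman_rubin(self._draws(mu))["mu[intercept]"] == pytest.approx(1.0)

    def test_separated_constant_chains_diverge(self):
        mu = np.stack([np.full((100, 1), -5.0), np.full((100, 1), 5.0)])
        assert ll.gelman_rubin(self._draws(mu))["mu[intercept]"] == np.inf

    def test_iid_normal_chains_below_1_05(self):
        rng = np.random.default_rng(16)
        mu = rng.normal(size=(2, 10_000, 1))
        assert ll.gelman_rubin(self._draws(mu))["mu[intercept]"] < 1.05

    def test_single_chain_rejected(self):
        mu = np.zeros((1, 100, 1))
        with pytest.raises(ValueError, match="2 chains"):
            ll.gelman_rubin(self._draws(mu))


class TestDIC:
    def test_degenerate_draws_give_zero_pd(self, toy_design):
        y = np.array([1, 0, 1])
        mu = np.tile(np.array([0.2, -0.1]), (2, 50, 1))
        dev = -2 * ll.log_likelihood(np.array([0.2, -0.1]), toy_design, y)
        draws = ll.PosteriorDraws(
            columns=list(toy_design.columns), random_set=[], mu=mu,
            sigma2=np.zeros((2, 50, 0)), deviance=np.full((2, 50), dev),
            beta_mean=np.zeros((3, 0)), n_obs=3,
        )
        result = ll.dic(draws, toy_design, y)
        assert result.pd == pytest.approx(0.0, abs=1e-9)
        assert result.dic == pytest.approx(dev)

    def test_identity_dic_equals_2dbar_minus_dhat(self):
        r = DICResult(dbar=100.0, dhat=95.0)
        assert r.pd == 5.0
        assert r.dic == 2 * 100.0 - 95.0

    def test_fixed_logit_pd_close_to_parameter_count(self, small_dataset):
        """For a near-normal posterior the effective number of parameters
        approximates the actual coefficient count (within 30%)."""
        dm, y = small_dataset.design, small_dataset.observations.y
        fx = ll.fit_fixed_logit(
            dm, y, None, ll.MCMCConfig(chains=2, iterations=4000, burnin=1500, seed=17)
        )
        result = ll.dic(fx, dm, y)
        p = len(dm.columns)
        assert abs(result.pd - p) / p < 0.3

    def test_mismatched_data_rejected(self, small_dataset, toy_design):
        dm, y = small_dataset.design, small_dataset.observations.y
        fx = ll.fit_fixed_logit(dm, y, None, ll.MCMCConfig(chains=2, iterations=200, burnin=100, seed=18))
        with pytest.raises(ValueError, match="different data"):
            ll.dic(fx, toy_design, np.array([1, 0, 1]))
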