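"""Learning rules: Bayesian moment matching, heuristics and controls."""

import math

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import ndtr

from driftlearn.learning import (
    BayesLearner,
    BayesLearnerParams,
    DeltaLearner,
    DeltaLearnerParams,
    RandomWeightParams,
    RandomWeightsPolicy,
    RLLearner,
    RLLearnerParams,
    ar1_transition,
    probit_posterior_moments,
)
from driftlearn.stimuli import OPTIMAL_WEIGHTS


def quadrature_moments(mu, sigma, s_tilde, c_star, n_nodes=150):
    """Independent oracle: Gauss-Hermite quadrature of the probit posterior."""
    nodes, weights = hermegauss(n_nodes)
    chol = np.linalg.cholesky(sigma)
    z1, z2 = np.meshgrid(nodes, nodes, indexing="ij")
    w2d = np.outer(weights, weights).ravel()
    pts = mu[None, :] + np.stack([z1.ravel(), z2.ravel()], axis=1) @ chol.T
    lik = ndtr(c_star * (pts @ s_tilde))
    wt = w2d * lik
    norm = wt.sum()
    mean = (wt[:, None] * pts).sum(axis=0) / norm
    centered = pts - mean
    cov = (wt[:, None, None] * np.einsum("ni,nj->nij", centered, centered)).sum(0) / norm
    return mean, cov


class TestProbitMomentMatching:
    def test_matches_quadrature_on_random_cases(self):
        rng = np.random.default_rng(8)
        worst = 0.0
        for _ in range(20):
            mu = rng.normal(0, 1, 2)
            a = rng.normal(0, 0.6, (2, 2))
            sigma = a @ a.T + 0.05 * np.eye(2)
            s = rng.normal(0, 1.5, 2)
            c_star = int(rng.choice([-1, 1]))
            m1, c1, _, _ = probit_posterior_moments(mu, sigma, s, c_star)
            m2, c2 = quadrature_moments(mu, sigma, s, c_star)
            worst = max(worst, np.abs(m1 - m2).max(), np.abs(c1 - c2).max())
        assert worst < 1e-3

    def test_zero_covariance_fixed_point(self):
        mu = np.array([0.7, -0.7])
        m, c, alpha, _ = probit_posterior_moments(mu, np.zeros((2, 2)),
                                                  np.array([1.0, 0.5]), 1)
        assert np.allclose(m, mu)
        assert np.allclose(c, 0.0)
        assert np.isfinite(alpha) and alpha > 0

    def test_alpha_positive_and_decreasing_in_confidence(self):
        sigma = 0.1 * np.eye(2)
        s = np.array([1.0, -0.5])
        alphas = []
        for scale in np.linspace(-2.0, 2.0, 15):
            mu = scale * s / np.linalg.norm(s)  # g grows with scale
            _, _, alpha, g = probit_posterior_moments(mu, sigma, s, 1)
            alphas.append((g, alpha))
        alphas.sort()
        gs, avals = zip(*alphas)
        assert all(a > 0 for a in avals)
        assert all(a1 >= a2 for a1, a2 in zip(avals, avals[1:]))

    def test_update_magnitude_ordering(self):
        # high-confidence error >> low-confidence trial > high-confidence correct
        sigma = 0.2 * np.eye(2)
        s = np.array([1.5, -1.0])
        mu = 1.2 * s / np.linalg.norm(s)
        def step(c_star, mu_=None):
            m, _, _, _ = probit_posterior_moments(mu_ if mu_ is not None else mu,
                                                  sigma, s, c_star)
            return np.linalg.norm(m - (mu_ if mu_ is not None else mu))
        high_conf_correct = step(1)
        high_conf_error = step(-1)
        low_conf = step(1, mu_=np.zeros(2))
        assert high_conf_error > low_conf > high_conf_correct

    def test_extreme_confidence_is_stable(self):
        # Phi(g) underflow region: log-domain hazard keeps the update finite
        mu = np.array([50.0, -50.0])
        s = np.array([1.0, -1.0])
        m, c, alpha, g = probit_posterior_moments(mu, 0.3 * np.eye(2), s, -1)
        assert np.all(np.isfinite(m)) and np.all(np.isfinite(c))
        assert g < -30 and alpha > 10


class TestAR1Transition:
    def test_identity_when_no_leak_no_diffusion(self):
        mu = np.array([0.3, -0.3])
        sigma = 0.1 * np.eye(2)
        m, s = ar1_transition(mu, sigma, 1.0, np.zeros(2))
        assert np.allclose(m, mu) and np.allclose(s, sigma)

    def test_steady_state_variance(self):
        gamma, q = 0.97, 3e-4
        sigma = np.zeros((2, 2))
        for _ in range(2000):
            _, sigma = ar1_transition(np.zeros(2), sigma, gamma, np.full(2, q))
        target = q / (1 - gamma**2)
        assert np.allclose(np.diag(sigma), target, atol=1e-6)

    def test_bias_channel_uses_its_own_diffusion(self):
        sigma = np.diag([0.01, 0.01, 0.02])
        _, out = ar1_transition(np.zeros(3), sigma, 0.9, np.array([1e-4, 1e-4, 5e-4]))
        assert out[2, 2] == pytest.approx(0.9**2 * 0.02 + 5e-4)


class TestBayesLearner:
    @pytest.mark.parametrize("variant,dim", [("weights", 2), ("bias", 1), ("both", 3)])
    def test_variant_dimensions(self, variant, dim):
        lrn = BayesLearner(BayesLearnerParams(variant=variant), sigma2_e=1.0)
        assert lrn.mu.shape == (dim,)
        assert lrn.sigma.shape == (dim, dim)

    def test_variant_wiring(self, rng):
        weights_only = BayesLearner(BayesLearnerParams(variant="weights"), 1.0)
        w, b = weights_only.policy(rng)
        assert b == 0.0
        bias_only = BayesLearner(BayesLearnerParams(variant="bias"), 1.0)
        w, b = bias_only.policy(rng)
        assert np.allclose(w, OPTIMAL_WEIGHTS)

    def test_sigma_stays_psd_over_many_updates(self, rng):
        lrn = BayesLearner(BayesLearnerParams(), sigma2_e=2.0)
        for k in range(300):
            s = rng.normal(0, 1.0, 2) + rng.choice([-1, 1]) * np.array([0.8, -0.8])
            lrn.observe(s, 0.5, 0.4 + rng.random(), 1, int(rng.choice([-1, 1])),
                        0.6, 0.6, rng)
            sigma = lrn.sigma
            assert np.allclose(sigma, sigma.T, atol=1e-10)
            assert np.linalg.eigvalsh(sigma)[0] > -1e-10

    def test_correct_feedback_is_win_stay(self, rng):
        # repeated correct-left feedback pushes the bias leftward (positive)
        lrn = BayesLearner(BayesLearnerParams(), sigma2_e=2.0)
        for _ in range(50):
            lrn.observe(np.array([0.3, 0.1]), 0.5, 0.5, 1, 1, 0.6, 0.6, rng)
        _, b = lrn.policy(rng)
        assert b > 0


class TestRLRule:
    def test_no_update_when_evidence_at_bound(self):
        lrn = RLLearner(RLLearnerParams(alpha=0.1, alpha_b=0.0))
        w0 = lrn.w.copy()
        # fast correct choice: e(t_d) = C* theta0 -> zero residual
        lrn.observe(np.array([0.5, -0.5]), 0.6, 0.01, 1, 1, 0.6, 0.6, None)
        assert np.allclose(lrn.w, w0)

    def test_zero_rates_freeze(self):
        lrn = RLLearner(RLLearnerParams(alpha=0.0, alpha_b=0.0))
        lrn.observe(np.array([1.0, 0.0]), -0.2, 0.5, -1, 1, 0.6, 0.6, None)
        assert np.allclose(lrn.w, OPTIMAL_WEIGHTS) and lrn.b == 0.0

    def test_weights_stay_normalized(self, rng):
        lrn = RLLearner(RLLearnerParams(alpha=0.3, alpha_b=0.1))
        for _ in range(100):
            lrn.observe(rng.normal(0, 1, 2), rng.normal(), 0.5, 1,
                        int(rng.choice([-1, 1])), 0.6, 0.6, rng)
            assert np.linalg.norm(lrn.w) == pytest.approx(1.0, abs=1e-12)


class TestDeltaRule:
    def test_no_update_after_correct(self):
        lrn = DeltaLearner(DeltaLearnerParams(alpha=0.2))
        w0, b0 = lrn.w.copy(), lrn.b
        lrn.observe(np.array([1.0, -1.0]), 0.6, 0.3, 1, 1, 0.6, 0.6, None)
        assert np.allclose(lrn.w, w0) and lrn.b == b0

    def test_error_update_magnitude_before_normalization(self):
        # incorrect at t_d ~ 0 (theta(t_d) = theta0): raw step 2 alpha C* s
        alpha, s = 0.05, np.array([0.4, -0.1])
        lrn = DeltaLearner(DeltaLearnerParams(alpha=alpha))
        w0 = lrn.w.copy()
        lrn.observe(s, 0.0, 1e-6, -1, 1, 0.6, 0.6, None)
        raw = w0 + alpha * 2.0 * s  # (C* - C) = 2 with C*=+1, C=-1
        assert np.allclose(lrn.w, raw / np.linalg.norm(raw))

    def test_collapsing_bound_shrinks_late_updates(self):
        s = np.array([0.4, -0.1])
        early = DeltaLearner(DeltaLearnerParams(alpha=0.05))
        late = DeltaLearner(DeltaLearnerParams(alpha=0.05))
        early.observe(s, 0.0, 0.1, -1, 1, 0.6, 0.6, None)   # theta(t_d) = theta0
        late.observe(s, 0.0, 2.0, -1, 1, 0.2, 0.6, None)    # collapsed bound
        w0 = OPTIMAL_WEIGHTS
        assert np.linalg.norm(late.w - w0) < np.linalg.norm(early.w - w0)


class TestRandomWeights:
    def test_zero_variance_is_exactly_optimal(self, rng):
        pol = RandomWeightsPolicy(RandomWeightParams(sigma2_rw=0.0, sigma2_rb=0.0))
        for _ in range(5):
            w, b = pol.policy(rng)
            assert np.allclose(w, OPTIMAL_WEIGHTS) and b == 0.0

    def test_sample_mean_near_optimum(self, rng):
        pol = RandomWeightsPolicy(RandomWeightParams(sigma2_rw=0.09, sigma2_rb=0.04))
        draws = np.array([np.append(*pol.policy(rng)) for _ in range(20000)])
        se = draws.std(axis=0) / math.sqrt(len(draws))
        target = np.append(OPTIMAL_WEIGHTS, 0.0)
        assert np.all(np.abs(draws.mean(axis=0) - target) < 3.5 * se)
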