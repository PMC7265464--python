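"""Trial-to-trial updating of category-boundary weights and bias.

Four rules are implemented, each as a small stateful learner object that a
session simulator queries for the current decision policy (weights ``w`` and
bias ``b``) and notifies after each trial's feedback:

* :class:`BayesLearner` — assumed-density-filtering approximation to the
  Bayes-optimal rule. The learner tracks a Gaussian belief N(mu, Sigma) over
  the latent boundary parameters, which are assumed to follow an AR(1)
  random walk across trials. Feedback (the revealed correct side ``C*``)
  enters through a probit likelihood ``Phi(C* w^T s~)`` of the normalized
  accumulated evidence, and the posterior is moment-matched back to a
  Gaussian. The resulting learning rate is confidence-weighted: small after
  high-confidence correct choices, moderate at low confidence, large after
  high-confidence errors.
* :class:`RLLearner` — reinforcement-learning point-estimate rule whose
  weight update is scaled by the residual ``C* - e(t_d)/theta0``; with a
  collapsing stopping bound this residual inherits a confidence modulation
  through elapsed time.
* :class:`DeltaLearner` — confidence-free delta rule: updates only after
  errors, scaled by ``theta(t_d)/theta0``.
* :class:`RandomWeightsPolicy` — non-learning control that redraws weights
  and bias independently every trial around the optimal values.

Sign conventions: choices and correct sides are coded +1 = left, -1 = right,
matching the accumulator convention that positive combined evidence means
"left". A correct-left trial therefore pushes ``w^T s`` positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

from .stimuli import OPTIMAL_WEIGHTS

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _std_normal_hazard(g: float) -> float:
    """z(g) = N(g|0,1) / Phi(g), evaluated in the log domain for stability."""
    return math.exp(-0.5 * g * g - _LOG_SQRT_2PI - log_ndtr(g))


def probit_posterior_moments(mu: np.ndarray, sigma: np.ndarray, s_tilde: np.ndarray,
                             c_star: int):
    """Exact first two moments of ``p(w) ∝ Phi(c* w^T s~) N(w | mu, Sigma)``.

    Returns ``(mu_post, sigma_post, alpha_w, g)`` where ``alpha_w`` is the
    effective learning rate ``z(g)/a`` with ``a = sqrt(1 + s~^T Sigma s~)``
    and ``g = c* mu^T s~ / a`` (the decision-confidence variable). For a
    probit likelihood these moment expressions are exact identities, so they
    agree with numerical quadrature of the posterior to integration accuracy.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    s_tilde = np.asarray(s_tilde, dtype=float)
    ss = sigma @ s_tilde
    a2 = 1.0 + float(s_tilde @ ss)
    a = math.sqrt(a2)
    g = c_star * float(mu @ s_tilde) / a
    z = _std_normal_hazard(g)
    alpha_w = z / a
    mu_post = mu + (c_star * alpha_w) * ss
    # Sherman-Morrison form of (Sigma^-1 + s~ s~^T)^-1 - Sigma, valid for
    # singular Sigma as well
    sigma_post = sigma - (z * (z + g) / a2) * np.outer(ss, ss)
    return mu_post, sigma_post, alpha_w, g


def ar1_transition(mu: np.ndarray, sigma: np.ndarray, gamma: float,
                   diffusion_diag: np.ndarray):
    """AR(1) belief propagation: mu <- gamma mu; Sigma <- gamma^2 Sigma + diag."""
    return gamma * mu, gamma**2 * sigma + np.diag(diffusion_diag)


def _symmetrize_floor(sigma: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    # float drift over ~1e5 sequential updates can break symmetry/PSD-ness
    sigma = 0.5 * (sigma + sigma.T)
    vals, vecs = np.linalg.eigh(sigma)
    if vals[0] < floor:
        sigma = (vecs * np.maximum(vals, floor)) @ vecs.T
    return sigma


@dataclass(frozen=True)
class BayesLearnerParams:
    """Hyperparameters of the Bayesian boundary learner.

    ``gamma_w`` is the AR(1) leak shared by weights and bias, ``sigma2_w`` /
    ``sigma2_b`` the per-trial diffusion variances, and ``sigma2_e`` the
    assumed across-trial difficulty variance (Var of w_opt . mu over the
    stimulus set; pass None to compute it from the session's stimulus set).
    ``variant`` selects which boundary parameters are learned.
    """

    gamma_w: float = 0.997
    sigma2_w: float = 0.30**2 * (1.0 - 0.997**2)
    sigma2_b: float = 0.20**2 * (1.0 - 0.997**2)
    sigma2_e: float | None = None
    variant: str = "both"  # "weights" | "bias" | "both"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_w < 1.0:
            raise ValueError("gamma_w must be in [0, 1)")
        if self.sigma2_w < 0 or self.sigma2_b < 0:
            raise ValueError("diffusion variances must be non-negative")
        if self.variant not in ("weights", "bias", "both"):
            raise ValueError("variant must be 'weights', 'bias' or 'both'")

    def steady_state_var_w(self) -> float:
        return self.sigma2_w / (1.0 - self.gamma_w**2)

    def steady_state_var_b(self) -> float:
        return self.sigma2_b / (1.0 - self.gamma_w**2)


class BayesLearner:
    """Gaussian belief over (w1, w2[, b]) updated by moment matching.

    The belief starts at the optimal boundary (animals are trained to
    proficiency before test sessions) with the AR(1) steady-state prior
    covariance. The bias enters as a third, constant evidence channel whose
    appended element is 1 before the ``s~`` normalization.
    """

    def __init__(self, params: BayesLearnerParams, sigma2_e: float):
        self.params = params
        self.sigma2_e = float(params.sigma2_e if params.sigma2_e is not None else sigma2_e)
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")
        self.reset()

    @property
    def dim(self) -> int:
        return {"weights": 2, "bias": 1, "both": 3}[self.params.variant]

    def reset(self) -> None:
        p = self.params
        if p.variant == "weights":
            self.mu = OPTIMAL_WEIGHTS.copy()
            diag = [p.steady_state_var_w()] * 2
        elif p.variant == "bias":
            self.mu = np.zeros(1)
            diag = [p.steady_state_var_b()]
        else:
            self.mu = np.append(OPTIMAL_WEIGHTS, 0.0)
            diag = [p.steady_state_var_w()] * 2 + [p.steady_state_var_b()]
        self.sigma = np.diag(diag)
        self._diffusion_diag = np.array(
            {
                "weights": [p.sigma2_w] * 2,
                "bias": [p.sigma2_b],
                "both": [p.sigma2_w, p.sigma2_w, p.sigma2_b],
            }[p.variant]
        )
        self._s_buf = np.ones(self.dim)  # constant bias channel stays 1
        self.trial_index = 0

    def policy(self, rng: np.random.Generator):
        v = self.params.variant
        if v == "weights":
            return self.mu.copy(), 0.0
        if v == "bias":
            return OPTIMAL_WEIGHTS.copy(), float(self.mu[0])
        return self.mu[:2].copy(), float(self.mu[2])

    def _augment(self, s_td: np.ndarray) -> np.ndarray:
        v = self.params.variant
        if v == "weights":
            return np.asarray(s_td, dtype=float)
        if v == "bias":
            return np.ones(1)
        return np.append(s_td, 1.0)

    def observe(self, s_td, e_td, t_d, choice, c_star, theta_td, theta0,
                rng: np.random.Generator) -> None:
        if t_d <= 0:
            raise ValueError("t_d must be positive")
        # hot loop: preallocated augmented-evidence buffer, in-place AR(1)
        buf = self._s_buf
        v = self.params.variant
        if v == "weights":
            buf[0], buf[1] = s_td[0], s_td[1]
        elif v == "both":
            buf[0], buf[1] = s_td[0], s_td[1]
        s_tilde = buf / math.sqrt(t_d + 1.0 / self.sigma2_e)
        mu, sigma = probit_posterior_moments(self.mu, self.sigma, s_tilde, c_star)[:2]
        gamma = self.params.gamma_w
        mu *= gamma
        sigma *= gamma * gamma
        sigma.flat[:: len(mu) + 1] += self._diffusion_diag
        # cheap symmetrization every trial; the full eigenvalue floor is a
        # slow safety net only needed rarely over very long sessions
        sigma = 0.5 * (sigma + sigma.T)
        self.trial_index += 1
        if self.trial_index % 1024 == 0:
            sigma = _symmetrize_floor(sigma)
        self.mu, self.sigma = mu, sigma

    def trace(self) -> dict:
        d = {}
        flat = self.sigma.flat
        if self.params.variant == "weights":
            d.update(var_w1=flat[0], var_w2=flat[3])
        elif self.params.variant == "bias":
            d.update(var_b=flat[0])
        else:
            d.update(var_w1=flat[0], var_w2=flat[4], var_b=flat[8])
        return d


@dataclass(frozen=True)
class RLLearnerParams:
    """Learning rates of the point-estimate RL rule."""

    alpha: float = 0.005
    alpha_b: float = 0.02

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.alpha_b < 0:
            raise ValueError("learning rates must be non-negative")


class RLLearner:
    """Point-estimate rule: w <- w + alpha (C* - e(t_d)/theta0) s, then renormalize."""

    def __init__(self, params: RLLearnerParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.w = OPTIMAL_WEIGHTS.copy()
        self.b = 0.0
        self.trial_index = 0

    def policy(self, rng):
        return self.w.copy(), self.b

    def observe(self, s_td, e_td, t_d, choice, c_star, theta_td, theta0, rng) -> None:
        if theta0 <= 0:
            raise ValueError("theta0 must be positive")
        w_plus = self.w + self.params.alpha * (c_star - e_td / theta0) * np.asarray(s_td)
        norm = np.linalg.norm(w_plus)
        if norm > 0:
            self.w = w_plus / norm
        self.b = self.b + self.params.alpha_b * (c_star - self.b / theta0)
        self.trial_index += 1

    def trace(self) -> dict:
        return {}


@dataclass(frozen=True)
class DeltaLearnerParams:
    """Learning rate of the confidence-free delta rule."""

    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


class DeltaLearner:
    """Delta rule: updates only on errors, scaled by theta(t_d)/theta0.

    The residual ``C* - C`` is 0 after correct choices and +-2 after errors;
    weights are renormalized to unit length after each update, the bias is
    updated analogously without the evidence factor.
    """

    def __init__(self, params: DeltaLearnerParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.w = OPTIMAL_WEIGHTS.copy()
        self.b = 0.0
        self.trial_index = 0

    def policy(self, rng):
        return self.w.copy(), self.b

    def observe(self, s_td, e_td, t_d, choice, c_star, theta_td, theta0, rng) -> None:
        if theta0 <= 0:
            raise ValueError("theta0 must be positive")
        residual = (c_star - choice) * theta_td / theta0
        w_plus = self.w + self.params.alpha * residual * np.asarray(s_td)
        norm = np.linalg.norm(w_plus)
        if norm > 0:
            self.w = w_plus / norm
        self.b = self.b + self.params.alpha * residual
        self.trial_index += 1

    def trace(self) -> dict:
        return {}


@dataclass(frozen=True)
class RandomWeightParams:
    """Per-trial draw variances of the non-learning fluctuation control."""

    sigma2_rw: float = 0.15**2
    sigma2_rb: float = 0.10**2

    def __post_init__(self) -> None:
        if self.sigma2_rw < 0 or self.sigma2_rb < 0:
            raise ValueError("variances must be non-negative")


class RandomWeightsPolicy:
    """Weights and bias redrawn independently every trial around the optimum.

    ``w ~ N((1,-1)/sqrt(2), sigma2_rw I)``, ``b ~ N(0, sigma2_rb)``. Because
    successive trials are independent, the policy carries no trial history
    and produces no sequential choice effects.
    """

    def __init__(self, params: RandomWeightParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.trial_index = 0

    def policy(self, rng: np.random.Generator):
        w = OPTIMAL_WEIGHTS + math.sqrt(self.params.sigma2_rw) * rng.standard_normal(2)
        b = math.sqrt(self.params.sigma2_rb) * rng.standard_normal()
        return w, float(b)

    def observe(self, s_td, e_td, t_d, choice, c_star, theta_td, theta0, rng) -> None:
        self.trial_index += 1

    def trace(self) -> dict:
        return {}


def draw_random_weights(params: RandomWeightParams, rng: np.random.Generator):
    """One trial's (w, b) draw from the random-weights control distribution."""
    return RandomWeightsPolicy(params).policy(rng)
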