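"""Two-channel drift-diffusion trial simulation and evidence reconstruction.

A trial accumulates two momentary-evidence channels (one per odorant) whose
means are the transduced drift rates; the decision variable is the weighted
combination ``e(t) = w1 s1(t) + w2 s2(t) + b`` diffusing against stopping
bounds ``+-theta(t)``. Simulation is performed on the equivalent
one-dimensional process ``x(t) = e(t) - b`` with drift ``w . mu`` and
diffusion variance ``||w||^2`` per unit time, against the shifted barriers
``{theta(t) - b, -theta(t) - b}``; the two-dimensional accumulated evidence
``s(t_d)`` is recovered afterwards by exact conditional-Gaussian sampling on
the decision hyperplane.

Reaction time adds a stochastic non-decision component:
``t_r = t_d + t_ND + eta`` with ``eta | t_d ~ N(0, (0.1 t_d)^2)``, floored at
zero. Lapses replace the *choice* (not the decision time) with a Bernoulli
draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .stimuli import (
    LEFT,
    OPTIMAL_WEIGHTS,
    RIGHT,
    Stimulus,
    StimulusSet,
    TransductionParams,
)

#: decisions still unresolved at this time are forced to the nearer boundary
MAX_DECISION_TIME = 10.0


@dataclass(frozen=True)
class BoundSpec:
    """Stopping-bound time course theta(t).

    shape "constant": theta0; "linear": theta0 + theta_slo * t floored at 0
    (theta_slo <= 0); "exponential": theta0 * exp(-t / tau_collapse).
    """

    shape: str = "constant"
    theta0: float = 0.6
    theta_slo: float = 0.0
    tau_collapse: float = np.inf

    def __post_init__(self) -> None:
        if self.shape not in ("constant", "linear", "exponential"):
            raise ValueError(f"unknown bound shape {self.shape!r}")
        if self.theta0 <= 0:
            raise ValueError("theta0 must be positive")
        if self.shape == "linear" and self.theta_slo > 0:
            raise ValueError("theta_slo must be <= 0")
        if self.shape == "exponential" and self.tau_collapse < 0:
            raise ValueError("tau_collapse must be >= 0")

    @property
    def is_constant(self) -> bool:
        return self.shape == "constant" or (
            self.shape == "linear" and self.theta_slo == 0.0
        ) or (self.shape == "exponential" and np.isinf(self.tau_collapse))

    def theta(self, t):
        """Bound height at time(s) t."""
        t = np.asarray(t, dtype=float)
        if self.shape == "linear":
            return np.maximum(self.theta0 + self.theta_slo * t, 0.0)
        if self.shape == "exponential":
            return self.theta0 * np.exp(-t / self.tau_collapse)
        return self.theta0 * np.ones_like(t)

    def theta_scalar(self, t: float) -> float:
        """Scalar bound height (hot-loop variant of :meth:`theta`)."""
        if self.shape == "linear":
            return max(self.theta0 + self.theta_slo * t, 0.0)
        if self.shape == "exponential":
            return self.theta0 * math.exp(-t / self.tau_collapse)
        return self.theta0

    def _kernel_shape(self) -> int:
        if self.is_constant:
            return _kernels.BOUND_CONSTANT
        if self.shape == "linear":
            return _kernels.BOUND_LINEAR
        return _kernels.BOUND_EXPONENTIAL


@dataclass(frozen=True)
class DecisionParams:
    """Category-boundary weights/bias, lapse model and non-decision time.

    ``lapse_rate`` is the probability that the choice is replaced by a
    Bernoulli draw choosing right with probability ``lapse_right_prob``
    (the decision time is still taken from the diffusion). ``nd_cv`` scales
    the non-decision-time noise SD as ``nd_cv * t_d``.
    """

    w: tuple[float, float] = (OPTIMAL_WEIGHTS[0], OPTIMAL_WEIGHTS[1])
    b: float = 0.0
    lapse_rate: float = 0.05
    lapse_right_prob: float = 0.5
    t_nd: float = 0.25
    nd_cv: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if not 0.0 <= self.lapse_right_prob <= 1.0:
            raise ValueError("lapse_right_prob must be in [0, 1]")
        if self.t_nd < 0:
            raise ValueError("t_nd must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.w, dtype=float)


@dataclass
class TrialOutcome:
    """Result of one simulated trial."""

    choice: int  # +1 left, -1 right
    correct: bool
    t_d: float
    t_r: float
    e_td: float
    s_td: np.ndarray
    lapsed: bool
    capped: bool


def reconstruct_evidence(e_td, t_d, stimulus: Stimulus,
                         transduction: TransductionParams, w, b,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample the 2-D accumulated evidence at decision time.

    Draws ``s ~ N(mu_vec * t_d, I * t_d)`` (unbounded diffusion) conditioned
    on the decision-plane constraint ``w . s + b = e_td``, by projecting an
    unconstrained sample onto the constraint line (exact conditional-Gaussian
    sampling). Requires ``||w|| > 0`` and ``t_d > 0``.
    """
    w = np.asarray(w, dtype=float)
    w2 = float(w @ w)
    if w2 == 0.0:
        raise ValueError("weights must not both be zero")
    if t_d <= 0:
        raise ValueError("t_d must be positive")
    mean = stimulus.drift_rates(transduction) * t_d
    u = mean + math.sqrt(t_d) * rng.standard_normal(2)
    return u + w * ((e_td - b - float(w @ u)) / w2)


def _reconstruct_evidence_batch(e_td, t_d, mu_vec, w, b, rng):
    # vectorized version for arrays of trials sharing w, b, mu_vec
    n = len(e_td)
    u = mu_vec[None, :] * t_d[:, None] + np.sqrt(t_d)[:, None] * rng.standard_normal((n, 2))
    w2 = float(w @ w)
    resid = (e_td - b - u @ w) / w2
    return u + resid[:, None] * w[None, :]


@dataclass
class Agent:
    """A complete simulable decision-maker: transduction + decision + bounds.

    ``learner`` is any object with the policy/observe interface from
    :mod:`driftlearn.learning`, or None for fixed weights. ``dt_constant``
    and ``dt_collapsing`` are the simulation step sizes for the two barrier
    families.
    """

    transduction: TransductionParams = field(default_factory=TransductionParams)
    decision: DecisionParams = field(default_factory=DecisionParams)
    bounds: BoundSpec = field(default_factory=BoundSpec)
    learner: object | None = None
    dt_constant: float = 1e-3
    dt_collapsing: float = 1e-3
    t_max: float = MAX_DECISION_TIME

    def reset(self) -> None:
        if self.learner is not None:
            self.learner.reset()


def _simulate_diffusion(agent: Agent, w: np.ndarray, b: float, mu_vec: np.ndarray,
                        seed: int):
    """One first-passage draw; returns (hit, t_d, e_td, capped)."""
    drift = float(w @ mu_vec)
    var = float(w @ w)
    if not (np.isfinite(drift) and np.isfinite(var)) or var <= 0:
        raise ValueError("drift/variance must be finite and variance positive")
    bounds = agent.bounds
    if abs(b) >= bounds.theta0:
        # the starting evidence e(0) = b already lies beyond a stopping
        # bound: the decision is immediate toward the bias side
        hit = 1 if b > 0 else -1
        return hit, agent.dt_constant, hit * bounds.theta0, False
    if bounds.is_constant:
        a_up = bounds.theta0 - b
        a_lo = bounds.theta0 + b
        hit, t_d, x_d = _kernels.fpt_constant(
            drift, var, a_up, a_lo, agent.dt_constant, agent.t_max, seed
        )
    else:
        hit, t_d, x_d = _kernels.fpt_collapsing(
            drift, var, b, bounds._kernel_shape(), bounds.theta0,
            bounds.theta_slo, bounds.tau_collapse, agent.dt_collapsing,
            agent.t_max, seed,
        )
    capped = hit == 0
    if capped:
        # force to the nearer boundary
        theta_t = bounds.theta_scalar(t_d)
        hit = 1 if (theta_t - b - x_d) <= (x_d + theta_t + b) else -1
        x_d = theta_t - b if hit == 1 else -theta_t - b
    return hit, t_d, x_d + b, capped


def _apply_lapse_and_rt(choice, t_d, decision: DecisionParams, rng):
    lapsed = rng.random() < decision.lapse_rate
    if lapsed:
        choice = RIGHT if rng.random() < decision.lapse_right_prob else LEFT
    eta = decision.nd_cv * t_d * rng.standard_normal()
    t_r = max(t_d + decision.t_nd + eta, 0.0)
    return choice, lapsed, t_r


def simulate_trial(stimulus: Stimulus, agent: Agent, rng: np.random.Generator,
                   seed: int | None = None) -> TrialOutcome:
    """Simulate a single trial (no learner update).

    ``rng`` drives lapse, non-decision noise and evidence reconstruction;
    ``seed`` (derived from it if omitted) drives the compiled diffusion
    kernel.
    """
    if seed is None:
        seed = int(rng.integers(2**31 - 1))
    w, b = agent.decision.weights, agent.decision.b
    if agent.learner is not None:
        w, b = agent.learner.policy(rng)
    mu_vec = stimulus.drift_rates(agent.transduction)
    hit, t_d, e_td, capped = _simulate_diffusion(agent, w, b, mu_vec, seed)
    choice, lapsed, t_r = _apply_lapse_and_rt(hit, t_d, agent.decision, rng)
    s_td = reconstruct_evidence(e_td, t_d, stimulus, agent.transduction, w, b, rng)
    return TrialOutcome(
        choice=choice,
        correct=choice == stimulus.correct_side,
        t_d=t_d,
        t_r=t_r,
        e_td=e_td,
        s_td=s_td,
        lapsed=lapsed,
        capped=capped,
    )


_TRIAL_COLUMNS = [
    "trial", "session", "stim_id", "task", "c_A", "c_B", "x", "difficulty",
    "contrast_pct", "total_conc", "correct_side", "choice", "correct",
    "lapsed", "capped", "t_d", "t_r", "e_td", "s1", "s2", "w1", "w2", "b",
]


def _stim_meta(stimulus: Stimulus) -> tuple:
    return (
        stimulus.stim_id, stimulus.task, stimulus.c_a, stimulus.c_b,
        stimulus.stimulus_axis(), stimulus.difficulty_level, stimulus.contrast,
        stimulus.total_concentration, stimulus.correct_side,
    )


def simulate_session(stimulus_set: StimulusSet, agent: Agent, n_trials: int,
                     seed: int, session: int = 0) -> pd.DataFrame:
    """Simulate a session of i.i.d.-presented stimuli with per-trial learning.

    Stimuli are drawn per the set's presentation probabilities; after each
    trial the agent's learner (if any) observes the outcome and updates its
    policy. Returns a tidy trial table including the per-trial weight/bias
    trace. Fixed-policy agents with constant bounds take a vectorized fast
    path; the learner path is strictly sequential. Both are deterministic
    given ``seed``.
    """
    if n_trials == 0:
        return pd.DataFrame(columns=_TRIAL_COLUMNS)
    rng = np.random.default_rng(seed)
    trial_seeds = (
        np.random.SeedSequence(seed).generate_state(n_trials + len(stimulus_set)) >> 1
    )
    stim_idx = stimulus_set.sample(rng, n_trials)

    if agent.learner is None and agent.bounds.is_constant:
        return _simulate_session_batch(
            stimulus_set, agent, stim_idx, rng, trial_seeds, session
        )

    rows = []
    extra_rows = []
    theta0 = agent.bounds.theta0
    drift_cache = [s.drift_rates(agent.transduction) for s in stimulus_set.stimuli]
    for k in range(n_trials):
        stim = stimulus_set.stimuli[stim_idx[k]]
        if agent.learner is not None:
            w, b = agent.learner.policy(rng)
        else:
            w, b = agent.decision.weights, agent.decision.b
        mu_vec = drift_cache[stim_idx[k]]
        hit, t_d, e_td, capped = _simulate_diffusion(
            agent, w, b, mu_vec, int(trial_seeds[k])
        )
        choice, lapsed, t_r = _apply_lapse_and_rt(hit, t_d, agent.decision, rng)
        # inline conditional-Gaussian reconstruction (hot loop)
        u = mu_vec * t_d + math.sqrt(t_d) * rng.standard_normal(2)
        s_td = u + w * ((e_td - b - float(w @ u)) / float(w @ w))
        if agent.learner is not None:
            extra_rows.append(agent.learner.trace())
            agent.learner.observe(
                s_td, e_td, t_d, choice, stim.correct_side,
                agent.bounds.theta_scalar(t_d), theta0, rng,
            )
        rows.append(
            (k, session) + _stim_meta(stim)
            + (choice, choice == stim.correct_side, lapsed, capped,
               t_d, t_r, e_td, s_td[0], s_td[1], w[0], w[1], b)
        )
    out = pd.DataFrame(rows, columns=_TRIAL_COLUMNS)
    if extra_rows and extra_rows[0]:
        out = pd.concat([out, pd.DataFrame(extra_rows)], axis=1)
    return out


def _simulate_session_batch(stimulus_set, agent, stim_idx, rng, trial_seeds, session):
    """Vectorized fixed-policy constant-bound path (per-stimulus batches)."""
    n = len(stim_idx)
    w, b = agent.decision.weights, agent.decision.b
    var = float(w @ w)
    a_up, a_lo = agent.bounds.theta0 - b, agent.bounds.theta0 + b
    if a_up <= 0 or a_lo <= 0:
        raise ValueError("fixed-policy sessions require |b| < theta0")
    hit = np.zeros(n, dtype=np.int64)
    t_d = np.zeros(n)
    e_td = np.zeros(n)
    s_td = np.zeros((n, 2))
    capped_all = np.zeros(n, dtype=bool)
    for j, stim in enumerate(stimulus_set.stimuli):
        mask = stim_idx == j
        m = int(mask.sum())
        if m == 0:
            continue
        mu_vec = stim.drift_rates(agent.transduction)
        drift = float(w @ mu_vec)
        h, t, x = _kernels.fpt_constant_batch(
            m, drift, var, a_up, a_lo, agent.dt_constant, agent.t_max,
            int(trial_seeds[len(stim_idx) + j]),
        )
        capped = h == 0
        if capped.any():
            nearer_up = (a_up - x[capped]) <= (x[capped] + a_lo)
            h[capped] = np.where(nearer_up, 1, -1)
            x[capped] = np.where(nearer_up, a_up, -a_lo)
        hit[mask] = h
        t_d[mask] = t
        e_td[mask] = x + b
        s_td[mask] = _reconstruct_evidence_batch(x + b, t, mu_vec, w, b, rng)
        capped_all[mask] = capped
    # lapses and reaction times (vectorized)
    lapsed = rng.random(n) < agent.decision.lapse_rate
    lapse_choice = np.where(
        rng.random(n) < agent.decision.lapse_right_prob, RIGHT, LEFT
    )
    choice = np.where(lapsed, lapse_choice, hit)
    eta = agent.decision.nd_cv * t_d * rng.standard_normal(n)
    t_r = np.maximum(t_d + agent.decision.t_nd + eta, 0.0)
    meta = np.array([_stim_meta(s) for s in stimulus_set.stimuli], dtype=object)
    sm = meta[stim_idx]
    correct_side = sm[:, 8].astype(int)
    out = pd.DataFrame(
        {
            "trial": np.arange(n),
            "session": session,
            "stim_id": sm[:, 0].astype(int),
            "task": sm[:, 1],
            "c_A": sm[:, 2].astype(float),
            "c_B": sm[:, 3].astype(float),
            "x": sm[:, 4].astype(float),
            "difficulty": sm[:, 5].astype(int),
            "contrast_pct": sm[:, 6].astype(float),
            "total_conc": sm[:, 7].astype(float),
            "correct_side": correct_side,
            "choice": choice,
            "correct": choice == correct_side,
            "lapsed": lapsed,
            "capped": capped_all,
            "t_d": t_d,
            "t_r": t_r,
            "e_td": e_td,
            "s1": s_td[:, 0],
            "s2": s_td[:, 1],
            "w1": w[0],
            "w2": w[1],
            "b": b,
        }
    )
    return out
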