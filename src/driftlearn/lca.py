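"""Leaky competing accumulator (LCA) race model — non-learning control.

Two rectified accumulators integrate the absolute evidence for each odorant,

    ds_i = (k c_i^beta - s_i / tau_leak - w_inh * s_{3-i}) dt + dW_i,

with mutual inhibition ``w_inh``, leak time constant ``tau_leak``, a unit
Wiener noise term (the noise scale is absorbed into ``k``) and a lower
reflection at 0. The first accumulator to reach the stopping bound theta(t)
triggers its choice (accumulator 1 -> left). Lapses, decision bias and
non-decision time are applied exactly as in the diffusion model. Two fitted
variants exist: constant bound (8 parameters) and linearly collapsing bound
(9 parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .ddm import BoundSpec, DecisionParams, TrialOutcome, _apply_lapse_and_rt
from .stimuli import LEFT, RIGHT, Stimulus, StimulusSet, TransductionParams


@dataclass(frozen=True)
class LCAParams:
    """Leak/inhibition parameters; transduction, bounds and lapses are shared
    with the diffusion model's parameter types."""

    tau_leak: float = 1.0
    w_inh: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_leak <= 0:
            raise ValueError("tau_leak must be positive")
        if self.w_inh < 0:
            raise ValueError("w_inh must be non-negative")


@dataclass
class LCAAgent:
    """Bundle of everything needed to simulate LCA trials."""

    lca: LCAParams = field(default_factory=LCAParams)
    transduction: TransductionParams = field(default_factory=TransductionParams)
    decision: DecisionParams = field(default_factory=DecisionParams)
    bounds: BoundSpec = field(default_factory=BoundSpec)
    dt: float = 1e-4
    t_max: float = 10.0


def simulate_lca_trial(stimulus: Stimulus, agent: LCAAgent,
                       rng: np.random.Generator,
                       seed: int | None = None) -> TrialOutcome:
    """Euler-simulate one LCA race trial (0.1 ms steps by default)."""
    if seed is None:
        seed = int(rng.integers(2**31 - 1))
    mu1, mu2 = stimulus.drift_rates(agent.transduction)
    hit, t_d, s1, s2 = _kernels.lca_trial(
        mu1, mu2, 1.0 / agent.lca.tau_leak, agent.lca.w_inh, agent.decision.b,
        agent.bounds._kernel_shape(), agent.bounds.theta0, agent.bounds.theta_slo,
        agent.bounds.tau_collapse, agent.dt, agent.t_max, seed,
    )
    capped = hit == 0
    if capped:
        hit = LEFT if s1 >= s2 else RIGHT
    choice, lapsed, t_r = _apply_lapse_and_rt(hit, t_d, agent.decision, rng)
    return TrialOutcome(
        choice=choice,
        correct=choice == stimulus.correct_side,
        t_d=t_d,
        t_r=t_r,
        e_td=s1 - s2,
        s_td=np.array([s1, s2]),
        lapsed=lapsed,
        capped=capped,
    )


def simulate_lca_session(stimulus_set: StimulusSet, agent: LCAAgent,
                         n_trials: int, seed: int, session: int = 0) -> pd.DataFrame:
    """Trial table for an LCA session, schema-compatible with the DDM table."""
    from .ddm import _TRIAL_COLUMNS, _stim_meta

    rng = np.random.default_rng(seed)
    trial_seeds = np.random.SeedSequence(seed).generate_state(max(n_trials, 1)) >> 1
    stim_idx = stimulus_set.sample(rng, n_trials) if n_trials else []
    rows = []
    for k in range(n_trials):
        stim = stimulus_set.stimuli[stim_idx[k]]
        out = simulate_lca_trial(stim, agent, rng, int(trial_seeds[k]))
        rows.append(
            (k, session) + _stim_meta(stim)
            + (out.choice, out.correct, out.lapsed, out.capped,
               out.t_d, out.t_r, out.e_td, out.s_td[0], out.s_td[1],
               np.nan, np.nan, agent.decision.b)
        )
    return pd.DataFrame(rows, columns=_TRIAL_COLUMNS)
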