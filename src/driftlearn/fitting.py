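"""Simulation-based maximum-likelihood fitting and model comparison.

Because collapsing bounds and sequential weight/bias updates rule out
closed-form reaction-time densities, the likelihood of a parameter vector is
evaluated by *simulating* the candidate model for a long trial sequence and
comparing per-condition summary statistics against the data:

* reaction times: the model's predicted mean RT per condition m is scored
  under a Gaussian centered on the observed mean with variance equal to the
  squared standard error ``sigma^2_t,m / n_m`` (a non-decision noise term
  ``(0.1 t_d,m)^2 / n_m`` is added to the variance, since the simulated and
  observed RTs both carry that stochasticity);
* choices: a Bernoulli kernel ``p^(P n) (1-p)^((1-P) n)`` of the observed
  correct counts under the model's predicted per-condition correct
  probability.

The "sequential" likelihood mode replaces the per-condition choice term with
per-cell terms conditioned on the previous trial (previous difficulty x
previous rewarded side x current condition) for trials following correct
choices, and a per-condition term pooled over previous conditions for trials
following errors.

Every likelihood evaluation reuses one frozen simulation seed (common random
numbers), so the surface seen by the derivative-free simplex search is
deterministic. Positive parameters are searched in log space, probabilities
in logit space. Model ranking uses BIC = -2 ln L + q ln n (plus AIC/AICc),
converted to a log10 marginal likelihood ``-BIC / (2 ln 10)`` whose pairwise
differences are log10 Bayes factors; a difference above 2 is conventionally
decisive.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .ddm import Agent, BoundSpec, DecisionParams, simulate_session
from .lca import LCAAgent, LCAParams, simulate_lca_session
from .learning import (
    BayesLearner,
    BayesLearnerParams,
    DeltaLearner,
    DeltaLearnerParams,
    RandomWeightsPolicy,
    RandomWeightParams,
    RLLearner,
)
from .stimuli import StimulusSet, TransductionParams
from .learning import RLLearnerParams


# ---------------------------------------------------------------------------
# condition summaries
# ---------------------------------------------------------------------------

def _condition_keys(trials: pd.DataFrame) -> list:
    # conditions are stimulus identities; the task label disambiguates
    # colliding stim_ids in joint (multi-task) fits
    if "task" in trials.columns:
        return ["task", "stim_id"]
    return ["stim_id"]


def summarize_conditions(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition trial count, correct fraction, RT mean and variance.

    Conditions are stimulus identities (``stim_id``; prefixed by task for
    multi-task tables). RT variance is the sample variance (ddof=1; NaN for
    single-trial conditions).
    """
    g = trials.groupby(_condition_keys(trials), observed=True)
    out = pd.DataFrame(
        {
            "n": g.size(),
            "p_correct": g["correct"].mean(),
            "rt_mean": g["t_r"].mean(),
            "rt_var": g["t_r"].var(ddof=1),
            "td_mean": g["t_d"].mean(),
        }
    )
    return out


def _sequential_cells(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Choice summaries conditioned on the previous trial.

    Returns (after-correct cells keyed by previous difficulty, previous
    choice and current stim_id; after-error cells keyed by current stim_id
    only — previous conditions are pooled because error trials are scarce).
    """
    t = trials
    if "prev_correct" not in t.columns:
        t = t.copy()
        g = t.groupby("session", observed=True)
        t["prev_correct"] = g["correct"].shift(1)
        t["prev_choice"] = g["choice"].shift(1)
        t["prev_difficulty"] = g["difficulty"].shift(1)
    keys = _condition_keys(t)
    after_c = t[t["prev_correct"] == True]  # noqa: E712
    cells_c = (
        after_c.groupby(["prev_difficulty", "prev_choice"] + keys, observed=True)
        ["correct"].agg(["size", "mean"])
        .rename(columns={"size": "n", "mean": "p_correct"})
    )
    after_e = t[t["prev_correct"] == False]  # noqa: E712
    cells_e = (
        after_e.groupby(keys, observed=True)["correct"].agg(["size", "mean"])
        .rename(columns={"size": "n", "mean": "p_correct"})
    )
    return cells_c, cells_e


@dataclass
class DataSummaries:
    """Pre-computed summaries of the behavioral data being fitted."""

    marginal: pd.DataFrame
    seq_correct: pd.DataFrame
    seq_error: pd.DataFrame
    n_trials: int
    tasks: tuple = ()

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "DataSummaries":
        cells_c, cells_e = _sequential_cells(trials)
        tasks = (tuple(trials["task"].unique()) if "task" in trials.columns
                 else ())
        return cls(summarize_conditions(trials), cells_c, cells_e, len(trials),
                   tasks)


# ---------------------------------------------------------------------------
# likelihood terms
# ---------------------------------------------------------------------------

def rt_loglik(model_mean, data_mean, data_var, n, extra_var: float = 0.0) -> float:
    """Log Gaussian density of the predicted mean RT under the data SEM.

    ``extra_var`` is divided by n alongside the data variance (used for the
    non-decision-time noise allowance).
    """
    if n < 2 or not data_var > 0:
        warnings.warn("condition with n < 2 or zero RT variance skipped")
        return 0.0
    var = (data_var + extra_var) / n
    return float(-0.5 * math.log(2.0 * math.pi * var)
                 - 0.5 * (model_mean - data_mean) ** 2 / var)


def choice_loglik(p_model, p_data, n, eps: float) -> float:
    """Log Bernoulli kernel of the observed correct counts under the model."""
    p = min(max(p_model, eps), 1.0 - eps)
    return float(n * (p_data * math.log(p) + (1.0 - p_data) * math.log(1.0 - p)))


def total_loglik(model_summaries: DataSummaries, data: DataSummaries,
                 mode: str = "marginal", n_sim: int = 100_000,
                 nd_cv: float = 0.1) -> float:
    """Summed per-condition log-likelihood of a simulated model vs the data.

    Conditions present in the data but absent (or degenerate) in the
    simulation contribute through clipped probabilities; a model condition
    missing entirely predicts p = 0.5.
    """
    eps = 1.0 / (n_sim + 1.0)
    ll = 0.0
    m = model_summaries.marginal
    for stim_id, row in data.marginal.iterrows():
        if stim_id in m.index:
            mr = m.loc[stim_id]
            # extra variance: non-decision-time noise allowance plus the
            # Monte-Carlo uncertainty of the simulated mean RT (the model
            # prediction is itself an estimate from finitely many trials).
            # The data-side variance proxies the model variance here: using
            # the model's own estimate would let high-variance parameter
            # regions soften their own misfit penalty.
            extra = (nd_cv * mr["td_mean"]) ** 2 + row["rt_var"] * row["n"] / mr["n"]
            ll += rt_loglik(mr["rt_mean"], row["rt_mean"], row["rt_var"], row["n"],
                            extra_var=extra)
        if mode == "marginal":
            p_model = m.loc[stim_id, "p_correct"] if stim_id in m.index else 0.5
            ll += choice_loglik(p_model, row["p_correct"], row["n"], eps)
    if mode == "sequential":
        mc, me = model_summaries.seq_correct, model_summaries.seq_error
        for key, row in data.seq_correct.iterrows():
            p_model = mc.loc[key, "p_correct"] if key in mc.index else 0.5
            ll += choice_loglik(p_model, row["p_correct"], row["n"], eps)
        for key, row in data.seq_error.iterrows():
            p_model = me.loc[key, "p_correct"] if key in me.index else 0.5
            ll += choice_loglik(p_model, row["p_correct"], row["n"], eps)
    return ll


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "k": "log", "beta": "log", "theta0": "log", "t_nd": "log",
    "lapse_rate": "logit", "lapse_right_prob": "logit", "b": "id",
    "theta_slo": "neglog", "tau_collapse": "log",
    "gamma_w": "logit", "sigma2_w": "log", "sigma2_b": "log",
    "alpha": "log", "alpha_b": "log",
    "sigma2_rw": "log", "sigma2_rb": "log",
    "tau_leak": "log", "w_inh": "log",
}


def _to_internal(name, value):
    t = _TRANSFORMS.get(name, "id")
    if t == "log":
        return math.log(max(value, 1e-12))
    if t == "neglog":
        return math.log(max(-value, 1e-12))
    if t == "logit":
        return float(logit(min(max(value, 1e-9), 1 - 1e-9)))
    return float(value)


def _from_internal(name, value):
    t = _TRANSFORMS.get(name, "id")
    if t == "log":
        return math.exp(value)
    if t == "neglog":
        return -math.exp(value)
    if t == "logit":
        return float(expit(value))
    return float(value)


@dataclass(frozen=True)
class ModelSpec:
    """A named, buildable agent family with default parameter values.

    ``defaults`` is the flat parameter dictionary; :meth:`build` turns such a
    dictionary into a fresh agent (learner state included) for a given
    stimulus set.
    """

    name: str
    defaults: dict

    def build(self, params: dict, stimulus_set: StimulusSet):
        p = {**self.defaults, **params}
        trans = TransductionParams(k=p["k"], beta=p["beta"])
        bounds = BoundSpec(
            shape=p.get("bound_shape", "constant"),
            theta0=p["theta0"],
            theta_slo=p.get("theta_slo", 0.0),
            tau_collapse=p.get("tau_collapse", np.inf),
        )
        decision = DecisionParams(
            b=p.get("b", 0.0),
            lapse_rate=p.get("lapse_rate", 0.05),
            lapse_right_prob=p.get("lapse_right_prob", 0.5),
            t_nd=p["t_nd"],
        )
        name = self.name
        if name.startswith("lca"):
            return LCAAgent(
                lca=LCAParams(tau_leak=p["tau_leak"], w_inh=p["w_inh"]),
                transduction=trans, decision=decision, bounds=bounds,
            )
        learner = None
        if name.startswith("bayes"):
            variant = {"bayes": "both", "bayes-weights": "weights",
                       "bayes-bias": "bias"}[name]
            learner = BayesLearner(
                BayesLearnerParams(
                    gamma_w=p["gamma_w"], sigma2_w=p.get("sigma2_w", 0.0),
                    sigma2_b=p.get("sigma2_b", 0.0), variant=variant,
                ),
                sigma2_e=stimulus_set.sigma_e2(trans),
            )
        elif name == "rl":
            learner = RLLearner(RLLearnerParams(alpha=p["alpha"], alpha_b=p["alpha_b"]))
        elif name == "delta":
            learner = DeltaLearner(DeltaLearnerParams(alpha=p["alpha"]))
        elif name == "random-weights":
            learner = RandomWeightsPolicy(
                RandomWeightParams(sigma2_rw=p["sigma2_rw"], sigma2_rb=p["sigma2_rb"])
            )
        elif name not in ("ddm", "ddm-collapse"):
            raise ValueError(f"unknown model {name!r}")
        return Agent(transduction=trans, decision=decision, bounds=bounds,
                     learner=learner)

    def simulate(self, params: dict, stimulus_set: StimulusSet, n_trials: int,
                 seed: int, session_trials: int | None = None) -> pd.DataFrame:
        """Simulate ``n_trials``; if ``session_trials`` is given, split them
        into independent sessions of that length with the learner state reset
        at each session start (the experimental protocol: testing happens in
        daily sessions of a few hundred trials)."""
        agent = self.build(params, stimulus_set)
        if isinstance(agent, LCAAgent):
            return simulate_lca_session(stimulus_set, agent, n_trials, seed)
        if not session_trials or session_trials >= n_trials:
            return simulate_session(stimulus_set, agent, n_trials, seed)
        n_sessions = (n_trials + session_trials - 1) // session_trials
        seeds = np.random.SeedSequence(seed).generate_state(n_sessions) >> 1
        frames = []
        done = 0
        for s in range(n_sessions):
            n = min(session_trials, n_trials - done)
            agent.reset()
            frames.append(
                simulate_session(stimulus_set, agent, n, int(seeds[s]), session=s)
            )
            done += n
        return pd.concat(frames, ignore_index=True)


_BASE = dict(k=10.0, beta=0.4, theta0=0.6, t_nd=0.25, lapse_rate=0.05)
# the confidence-weighted learning family uses a linearly collapsing stopping
# bound (the full model has 10 parameters: 6 base + collapse + 3 learning)
_COLLAPSE = dict(bound_shape="linear", theta_slo=-0.2)
_BAYES = dict(gamma_w=0.997, sigma2_w=0.30**2 * (1 - 0.997**2),
              sigma2_b=0.20**2 * (1 - 0.997**2))

MODEL_DEFAULTS = {
    "ddm": dict(_BASE),
    "ddm-collapse": dict(_BASE, **_COLLAPSE),
    "bayes": dict(_BASE, **_COLLAPSE, **_BAYES),
    "bayes-weights": dict(_BASE, **_COLLAPSE, gamma_w=_BAYES["gamma_w"],
                          sigma2_w=_BAYES["sigma2_w"], sigma2_b=0.0),
    "bayes-bias": dict(_BASE, **_COLLAPSE, gamma_w=_BAYES["gamma_w"], sigma2_w=0.0,
                       sigma2_b=_BAYES["sigma2_b"]),
    "rl": dict(_BASE, bound_shape="exponential", tau_collapse=2.0,
               alpha=0.005, alpha_b=0.02),
    "delta": dict(_BASE, **_COLLAPSE, alpha=0.01),
    "random-weights": dict(_BASE, **_COLLAPSE, sigma2_rw=0.30**2, sigma2_rb=0.20**2),
    "lca": dict(_BASE, tau_leak=1.0, w_inh=0.5),
    "lca-collapse": dict(_BASE, tau_leak=1.0, w_inh=0.5,
                         bound_shape="linear", theta_slo=-0.2),
}


def make_model(name: str, **overrides) -> ModelSpec:
    """Model registry lookup; ``overrides`` replace default parameter values."""
    if name not in MODEL_DEFAULTS:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_DEFAULTS)}")
    return ModelSpec(name=name, defaults={**MODEL_DEFAULTS[name], **overrides})


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Controls for the simulation-based likelihood search.

    ``n_sim`` simulated trials per likelihood evaluation; ``sim_seed`` the
    frozen per-evaluation seed; ``mode`` the likelihood flavor; ``n_starts``
    simplex restarts jittered (SD ``jitter`` in transformed space) around the
    initial point; ``maxfev`` function-evaluation budget per start.
    """

    n_sim: int = 100_000
    sim_seed: int = 1234
    mode: str = "marginal"
    session_trials: int = 300
    n_starts: int = 5
    jitter: float = 0.2
    maxfev: int = 200
    xatol: float = 1e-3
    fatol: float = 1e-2


@dataclass
class FitResult:
    """Fitted parameters with log-likelihood and information criteria."""

    model: str
    params: dict
    free_names: list
    loglik: float
    n_params: int
    n_trials: int
    bic: float
    aic: float
    aicc: float
    log10_marginal: float
    n_evaluations: int
    converged: bool
    config: FitConfig
    runtime_s: float = 0.0

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "params": self.params,
            "free_names": list(self.free_names),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_trials": self.n_trials,
            "bic": self.bic,
            "aic": self.aic,
            "aicc": self.aicc,
            "log10_marginal": self.log10_marginal,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "n_sim": self.config.n_sim,
            "sim_seed": self.config.sim_seed,
            "mode": self.config.mode,
            "runtime_s": self.runtime_s,
        }
        return d


def information_criteria(loglik: float, q: int, n: int) -> dict:
    """BIC, AIC, AICc and the BIC-based log10 marginal likelihood."""
    bic = -2.0 * loglik + q * math.log(n)
    aic = -2.0 * loglik + 2.0 * q
    aicc = aic + (2.0 * q * (q + 1) / (n - q - 1) if n > q + 1 else np.inf)
    return {
        "bic": bic,
        "aic": aic,
        "aicc": aicc,
        "log10_marginal": -0.5 * bic / math.log(10.0),
    }


def model_loglik(model: ModelSpec, params: dict, data: DataSummaries,
                 stimulus_set, config: FitConfig) -> float:
    """Simulate the model (frozen seeds) and score it against the data.

    ``stimulus_set`` may be a single set or, for joint fits across tasks, a
    ``{task: StimulusSet}`` mapping covering every task in the data; the
    model is simulated for ``n_sim`` trials per task.
    """
    if isinstance(stimulus_set, dict):
        sets = [stimulus_set[t] for t in data.tasks]
    else:
        sets = [stimulus_set]
    sims = [model.simulate(params, s, config.n_sim, config.sim_seed + j,
                           session_trials=config.session_trials)
            for j, s in enumerate(sets)]
    sim = pd.concat(sims, ignore_index=True) if len(sims) > 1 else sims[0]
    ms = DataSummaries.from_trials(sim) if config.mode == "sequential" else \
        DataSummaries(summarize_conditions(sim), None, None, len(sim))
    return total_loglik(ms, data, mode=config.mode, n_sim=config.n_sim)


def fit_model(model: ModelSpec, trials: pd.DataFrame, free: list[str],
              stimulus_set: StimulusSet, config: FitConfig | None = None,
              init: dict | None = None) -> FitResult:
    """Maximize the simulation-based likelihood over ``free`` parameters.

    Derivative-free simplex (Nelder-Mead) search in transformed parameter
    space with frozen per-evaluation simulation seeds; multi-start jitter
    around the initialization (model defaults unless ``init`` given); the
    best start wins. Non-converged searches return the best point found,
    flagged in the result.
    """
    config = config or FitConfig()
    t_start = time.perf_counter()
    data = DataSummaries.from_trials(trials)
    init_params = {**model.defaults, **(init or {})}
    x0 = np.array([_to_internal(f, init_params[f]) for f in free])
    rng = np.random.default_rng(config.sim_seed)
    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        params = {f: _from_internal(f, xi) for f, xi in zip(free, x)}
        try:
            return -model_loglik(model, params, data, stimulus_set, config)
        except (ValueError, FloatingPointError):
            return 1e12

    best = None
    converged = False
    for start in range(config.n_starts):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, config.jitter, len(x0))
        res = minimize(objective, xs, method="Nelder-Mead",
                       options={"maxfev": config.maxfev, "xatol": config.xatol,
                                "fatol": config.fatol})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    params = {**init_params,
              **{f: _from_internal(f, xi) for f, xi in zip(free, best.x)}}
    loglik = -float(best.fun)
    crit = information_criteria(loglik, len(free), data.n_trials)
    return FitResult(
        model=model.name,
        params=params,
        free_names=list(free),
        loglik=loglik,
        n_params=len(free),
        n_trials=data.n_trials,
        n_evaluations=n_eval,
        converged=converged,
        config=config,
        runtime_s=time.perf_counter() - t_start,
        **crit,
    )


def compare_models(results: list[FitResult]) -> pd.DataFrame:
    """Rank fit results by BIC and report log10 Bayes factors vs the best.

    All results must be fits of the same data (identical trial counts).
    ``decisive`` flags models whose log10 Bayes factor against the winner
    exceeds 2.
    """
    if len({r.n_trials for r in results}) != 1:
        raise ValueError("results were fitted on different numbers of trials")
    rows = sorted(results, key=lambda r: r.bic)
    best = rows[0]
    return pd.DataFrame(
        {
            "model": [r.model for r in rows],
            "loglik": [r.loglik for r in rows],
            "n_params": [r.n_params for r in rows],
            "bic": [r.bic for r in rows],
            "aic": [r.aic for r in rows],
            "aicc": [r.aicc for r in rows],
            "log10_marginal": [r.log10_marginal for r in rows],
            "log10_bf_vs_best": [best.log10_marginal - r.log10_marginal
                                 for r in rows],
            "decisive": [best.log10_marginal - r.log10_marginal > 2.0
                         for r in rows],
        }
    )
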