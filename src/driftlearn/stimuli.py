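"""Stimulus spaces and sensory transduction for two-alternative olfactory decisions.

Three tasks share a common stimulus representation (a pair of odorant
concentrations):

* **identification** — a single pure odorant per trial, diluted over
  10^-1 .. 10^-4 (v/v); difficulty is absolute concentration.
* **categorization** — binary mixtures at a fixed total concentration;
  difficulty is the mixture contrast |cA - cB| / (cA + cB).
* **interleaved** — the full cross of 8 mixture contrasts x 4 total
  concentrations (32 stimuli), combining both difficulty axes.

Concentrations are mapped to mean drift rates through a power law
``mu_i = k * c_i**beta`` with momentary-evidence SD ``sigma`` fixed at 1, so
``k * c**beta`` is the per-channel signal-to-noise rate.

The module also implements the two adaptive algorithms used during animal
training: an exponentially-smoothed online bias estimate feeding a logistic
anti-bias side probability, and a geometric-CDF-shaped difficulty schedule
driven by running performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LEFT = 1
RIGHT = -1

#: canonical category-boundary weights: w = (1, -1)/sqrt(2), ||w|| = 1
OPTIMAL_WEIGHTS = np.array([1.0, -1.0]) / math.sqrt(2.0)

IDENTIFICATION_DILUTIONS = (1e-1, 1e-2, 1e-3, 1e-4)
#: mixture ratios (fraction of odor A) for the 8-stimulus categorization set;
#: complements are generated automatically
CATEGORIZATION_RATIOS = (0.0, 0.20, 0.32, 0.44)
DEFAULT_TOTAL_CONCENTRATION = 1e-1


@dataclass(frozen=True)
class TransductionParams:
    """Power-law mapping of odorant concentration to mean drift rate.

    ``mu(c) = k * c**beta``; ``sigma`` is the SD of the momentary evidence per
    unit time and is fixed at 1 so that drift rates are in SNR units.
    """

    k: float = 10.0
    beta: float = 0.4
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.beta <= 0:
            raise ValueError("k and beta must be positive")
        if self.sigma != 1.0:
            raise ValueError("sigma is fixed at 1 (drift rates are in SNR units)")


def transduce(c, params: TransductionParams):
    """Mean drift rate ``k * c**beta`` for concentration(s) ``c`` (v/v, >= 0)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return params.k * np.power(c, params.beta)


@dataclass(frozen=True)
class Stimulus:
    """One odor stimulus: a concentration pair plus task metadata.

    ``difficulty_level`` is ordinal 1 (easiest) .. 4 (hardest): the dilution
    step for identification, the contrast rank for categorization/interleaved.
    ``contrast`` is the percent mixture contrast |cA-cB|/(cA+cB)*100.
    """

    stim_id: int
    task: str
    c_a: float
    c_b: float
    correct_side: int  # LEFT (+1) or RIGHT (-1)
    difficulty_level: int
    contrast: float = field(default=np.nan)
    total_concentration: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.c_a < 0 or self.c_b < 0:
            raise ValueError("concentrations must be non-negative")
        if self.c_a == 0 and self.c_b == 0:
            raise ValueError("at least one concentration must be positive")
        if self.correct_side not in (LEFT, RIGHT):
            raise ValueError("correct_side must be +1 (left) or -1 (right)")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([self.c_a, self.c_b])

    def drift_rates(self, transduction: TransductionParams) -> np.ndarray:
        return transduce(self.concentrations, transduction)

    def mirrored(self, stim_id: int | None = None) -> "Stimulus":
        """The left/right mirrored stimulus (cB, cA)."""
        return replace(
            self,
            stim_id=self.stim_id if stim_id is None else stim_id,
            c_a=self.c_b,
            c_b=self.c_a,
            correct_side=-self.correct_side,
        )

    def stimulus_axis(self) -> float:
        """Signed stimulus value on a common [-1, 1] psychometric axis.

        Categorization/interleaved: signed mixture contrast (cA-cB)/(cA+cB),
        positive toward odor A (left). Identification: sign * (5 + log10 c)/4,
        which maps the 10^-4..10^-1 dilutions to +-{0.25, 0.5, 0.75, 1}.
        """
        if self.task == "identification":
            c = max(self.c_a, self.c_b)
            sign = 1.0 if self.c_a >= self.c_b else -1.0
            return sign * (5.0 + math.log10(c)) / 4.0
        return (self.c_a - self.c_b) / (self.c_a + self.c_b)


@dataclass(frozen=True)
class StimulusSet:
    """Ordered collection of stimuli with per-stimulus presentation probability."""

    task: str
    stimuli: tuple[Stimulus, ...]
    presentation_probability: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.stimuli:
            raise ValueError("stimulus set must not be empty")
        if not self.presentation_probability:
            p = (1.0 / len(self.stimuli),) * len(self.stimuli)
            object.__setattr__(self, "presentation_probability", p)
        p = np.asarray(self.presentation_probability)
        if len(p) != len(self.stimuli) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("presentation probabilities must match stimuli and sum to 1")

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` stimulus indices i.i.d. per presentation probability."""
        return rng.choice(len(self.stimuli), size=size, p=self.presentation_probability)

    def sigma_e2(self, transduction: TransductionParams) -> float:
        """Across-trial decision-difficulty variance: Var of w_opt . mu over the set.

        This is the default value of the Bayes learner's assumed difficulty
        variance (the learner is assumed to know the stimulus statistics).
        """
        proj = np.array(
            [OPTIMAL_WEIGHTS @ s.drift_rates(transduction) for s in self.stimuli]
        )
        p = np.asarray(self.presentation_probability)
        mean = p @ proj
        return float(p @ (proj - mean) ** 2)

    def to_frame(self) -> pd.DataFrame:
        """Serialize as a tidy table (one row per stimulus)."""
        return pd.DataFrame(
            {
                "stim_id": [s.stim_id for s in self.stimuli],
                "task": [s.task for s in self.stimuli],
                "c_A": [s.c_a for s in self.stimuli],
                "c_B": [s.c_b for s in self.stimuli],
                "correct_side": [s.correct_side for s in self.stimuli],
                "contrast_pct": [s.contrast for s in self.stimuli],
                "total_conc": [s.total_concentration for s in self.stimuli],
                "difficulty_level": [s.difficulty_level for s in self.stimuli],
            }
        )


def _categorization_pairs(ratios, total):
    """Yield (cA, cB, contrast_pct, level) for each ratio and its complement."""
    # ratios are fractions of odor A <= 0.5; smaller ratio = larger contrast = easier
    for level, r in enumerate(sorted(ratios), start=1):
        contrast = abs(1.0 - 2.0 * r) * 100.0
        # complement first (A-majority -> left), then the ratio itself (B-majority)
        yield (1.0 - r) * total, r * total, contrast, level
        yield r * total, (1.0 - r) * total, contrast, level


def build_stimulus_set(
    task: str,
    *,
    dilutions=IDENTIFICATION_DILUTIONS,
    ratios=CATEGORIZATION_RATIOS,
    total_concentration: float = DEFAULT_TOTAL_CONCENTRATION,
) -> StimulusSet:
    """Construct the canonical stimulus set for a task.

    identification -> 8 pure-odor stimuli (4 dilutions x 2 sides);
    categorization -> 8 binary mixtures (4 contrasts and complements) summing
    to ``total_concentration``; interleaved -> 32 stimuli (8 contrasts x 4
    totals), whose 100%-contrast stimuli at the highest total equal the
    identification 10^-1 pair.
    """
    stimuli: list[Stimulus] = []
    if task == "identification":
        for level, c in enumerate(sorted(dilutions, reverse=True), start=1):
            stimuli.append(
                Stimulus(len(stimuli), task, c, 0.0, LEFT, level, 100.0, c)
            )
            stimuli.append(
                Stimulus(len(stimuli), task, 0.0, c, RIGHT, level, 100.0, c)
            )
    elif task == "categorization":
        if any(r > 0.5 for r in ratios):
            raise ValueError("ratios must be the minority fraction (<= 0.5)")
        for c_a, c_b, contrast, level in _categorization_pairs(ratios, total_concentration):
            side = LEFT if c_a > c_b else RIGHT
            stimuli.append(
                Stimulus(len(stimuli), task, c_a, c_b, side, level, contrast, total_concentration)
            )
    elif task == "interleaved":
        for total in sorted(dilutions, reverse=True):
            for c_a, c_b, contrast, level in _categorization_pairs(ratios, total):
                side = LEFT if c_a > c_b else RIGHT
                stimuli.append(
                    Stimulus(len(stimuli), task, c_a, c_b, side, level, contrast, total)
                )
    else:
        raise ValueError(f"unknown task {task!r}")
    return StimulusSet(task=task, stimuli=tuple(stimuli))


# ---------------------------------------------------------------------------
# adaptive training algorithms
# ---------------------------------------------------------------------------

@dataclass
class AdaptiveTrainerState:
    """Running estimates driving the anti-bias and difficulty schedules.

    ``b_t``/``p_t`` are exponentially-smoothed estimates of choice bias
    (fraction left) and performance (fraction correct); both start at 0.5
    (unbiased prior before data). ``tau_decay`` is the smoothing memory,
    ``b0``/``p0`` the targets, ``gamma_nl`` the logistic nonlinearity scale,
    and ``n_levels`` the number of difficulty levels in the session.
    """

    b_t: float = 0.5
    p_t: float = 0.5
    tau_decay: float = 0.05
    b0: float = 0.5
    p0: float = 0.95
    gamma_nl: float = 0.25
    n_levels: int = 4


def update_online_bias(state: AdaptiveTrainerState, choice: float) -> float:
    """Exponential update ``b_t = (1 - tau) * C_t + tau * b_{t-1}``.

    ``choice`` is coded 1 for left, 0 for right. Returns (and stores) the
    updated bias estimate. The same recursion updates the performance
    estimate when fed the trial outcome instead of the choice.
    """
    if choice not in (0, 1):
        raise ValueError("choice must be 0 (right) or 1 (left)")
    state.b_t = (1.0 - state.tau_decay) * choice + state.tau_decay * state.b_t
    return state.b_t


def update_online_performance(state: AdaptiveTrainerState, outcome: float) -> float:
    """Same recursion as :func:`update_online_bias` on the trial outcome."""
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 (error) or 1 (correct)")
    state.p_t = (1.0 - state.tau_decay) * outcome + state.tau_decay * state.p_t
    return state.p_t


def antibias_side_probability(b_t: float, b0: float = 0.5, gamma_nl: float = 0.25) -> float:
    """Probability of presenting a right-rewarded stimulus given measured bias.

    ``p_R = 1 - 1 / (1 + exp((b_t - b0) / gamma))``: a leftward bias
    (``b_t > b0``) raises the probability of right-side stimuli.
    """
    if gamma_nl <= 0:
        raise ValueError("gamma_nl must be positive")
    return 1.0 - 1.0 / (1.0 + math.exp((b_t - b0) / gamma_nl))


def _geom_cdf(i: np.ndarray, p: float) -> np.ndarray:
    # geometric CDF with support starting at 1: P(X <= i) = 1 - (1-p)**i
    return 1.0 - np.power(1.0 - p, i)


def difficulty_parameter(p_t: float, p0: float = 0.95, gamma_nl: float = 0.25) -> float:
    """Difficulty control ``delta = -1 + 2 / (1 + exp((p_t - p0)/gamma))`` in (-1, 1)."""
    return -1.0 + 2.0 / (1.0 + math.exp((p_t - p0) / gamma_nl))


def difficulty_distribution(
    p_t: float, p0: float = 0.95, gamma_nl: float = 0.25, n_levels: int = 4
) -> np.ndarray:
    """Per-difficulty presentation probabilities from running performance.

    The weights are the geometric-CDF tails ``1 - GeomCDF(i, |delta|)``
    normalized over levels 1..N. For ``delta > 0`` (performance above target)
    index 1 is the easiest level, so mass shifts toward *harder* stimuli; for
    ``delta < 0`` the index order is reversed. ``delta = 0`` gives a uniform
    distribution (all geometric tails equal 1). Index 0 of the returned
    vector is difficulty level 1 (easiest).
    """
    if n_levels == 1:
        return np.array([1.0])
    if n_levels not in (2, 3, 4):
        raise ValueError("n_levels must be 1..4")
    delta = difficulty_parameter(p_t, p0, gamma_nl)
    i = np.arange(1, n_levels + 1, dtype=float)
    weights = 1.0 - _geom_cdf(i, abs(delta))
    if weights.sum() == 0.0:
        # |delta| -> 1 limit: the geometric tails vanish but their ratios
        # concentrate all mass on index 1
        weights = np.zeros(n_levels)
        weights[0] = 1.0
    if delta < 0:
        weights = weights[::-1]
    return weights / weights.sum()
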