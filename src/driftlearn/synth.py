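"""Synthetic multi-animal behavioral datasets.

The rat data behind the original study are not publicly deposited, so this
module generates complete stand-in datasets with known ground truth: a small
cohort of simulated "rats", each running daily sessions of 250-400 trials on
the identification / categorization / interleaved tasks, with per-animal
parameters jittered log-normally around the configured agent. The output is
the package's standard trial-table CSV plus a JSON manifest of the true
parameters and seeds, so that fitting and analysis stages can be validated
end-to-end against known generators.

An optional invalid-trial process mimics the exclusion of early-withdrawal
trials: a configurable fraction of trials is marked invalid (with the
odor-onset delay drawn uniformly from [0.3, 0.6] s recorded for
bookkeeping) and excluded from analysis tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import ModelSpec, make_model
from .stimuli import build_stimulus_set

#: parameters never jittered across animals (structural / variance-like)
_NO_JITTER = {"bound_shape"}


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Layout of a synthetic behavioral study.

    ``trials_per_session`` spans the realistic single-session range; the
    per-animal parameter jitter is log-normal with SD ``jitter_sd`` (applied
    to positive parameters only). ``invalid_fraction`` of trials is dropped
    as invalid (early withdrawal emulation).
    """

    model: str = "bayes"
    overrides: dict = field(default_factory=dict)
    tasks: tuple[str, ...] = ("identification", "categorization")
    n_rats: int = 4
    sessions_per_rat: int = 10
    trials_per_session: tuple[int, int] = (250, 400)
    jitter_sd: float = 0.10
    invalid_fraction: float = 0.058
    seed: int = 0


def _jitter_params(defaults: dict, rng: np.random.Generator, sd: float) -> dict:
    out = {}
    for name, value in defaults.items():
        if sd > 0 and name not in _NO_JITTER and isinstance(value, float) and value > 0:
            out[name] = float(value * rng.lognormal(0.0, sd))
        else:
            out[name] = value
    return out


def generate_study(spec: SyntheticStudySpec):
    """Generate the full study: one trial table + ground-truth manifest.

    Returns ``(trials, manifest)``. Each rat gets deterministically derived
    seeds and its own jittered parameter set; sessions alternate through the
    requested tasks. Learner state resets at each session start. Invalid
    trials remain in the table flagged ``valid == False``.
    """
    root = np.random.SeedSequence(spec.seed)
    rat_seeds = root.spawn(spec.n_rats)
    model = make_model(spec.model, **spec.overrides)
    frames = []
    manifest = {
        "spec": {**asdict(spec), "trials_per_session": list(spec.trials_per_session)},
        "rats": [],
    }
    for rat in range(spec.n_rats):
        seq = rat_seeds[rat]
        rng = np.random.default_rng(seq)
        params = _jitter_params(model.defaults, rng, spec.jitter_sd)
        rat_model = ModelSpec(name=model.name, defaults=params)
        session_seeds = seq.generate_state(spec.sessions_per_rat) >> 1
        manifest["rats"].append(
            {"rat": rat, "params": params,
             "session_seeds": [int(s) for s in session_seeds]}
        )
        for sess in range(spec.sessions_per_rat):
            task = spec.tasks[sess % len(spec.tasks)]
            stimulus_set = build_stimulus_set(task)
            n = int(rng.integers(spec.trials_per_session[0],
                                 spec.trials_per_session[1] + 1))
            df = rat_model.simulate(params, stimulus_set, n, int(session_seeds[sess]))
            df["rat"] = rat
            df["session"] = sess
            df["d_odor"] = rng.uniform(0.3, 0.6, len(df))
            df["valid"] = rng.random(len(df)) >= spec.invalid_fraction
            frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    return trials, manifest


def write_study(spec: SyntheticStudySpec, outdir) -> Path:
    """Generate and write ``trials.csv`` + ``manifest.json`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials, manifest = generate_study(spec)
    trials.to_csv(outdir / "trials.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def valid_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop invalid trials (the analysis-side exclusion)."""
    if "valid" in trials.columns:
        return trials[trials["valid"]].reset_index(drop=True)
    return trials


def make_fixtures(outdir=None, n_trials: int = 4000, seed: int = 1) -> dict:
    """Small single-session datasets per model family for fast tests.

    Returns ``{(model, task): trials}`` with <= ``n_trials`` trials each;
    writes CSVs when ``outdir`` is given.
    """
    cases = [
        ("ddm", "identification"),
        ("bayes", "categorization"),
        ("bayes-bias", "identification"),
        ("random-weights", "categorization"),
        ("delta", "categorization"),
    ]
    out = {}
    for i, (model_name, task) in enumerate(cases):
        model = make_model(model_name)
        stimulus_set = build_stimulus_set(task)
        df = model.simulate(model.defaults, stimulus_set, n_trials, seed + i)
        out[(model_name, task)] = df
        if outdir is not None:
            Path(outdir).mkdir(parents=True, exist_ok=True)
            df.to_csv(Path(outdir) / f"{model_name}_{task}.csv", index=False)
    return out
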