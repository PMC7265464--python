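"""Shared fixtures: small simulated trial tables reused across test modules.

Everything is generated at test time from fixed seeds; session scope keeps
the per-run simulation cost down.
"""

from __future__ import annotations

import numpy as np
import pytest

from driftlearn import Agent, build_stimulus_set, make_model, simulate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cat_set():
    return build_stimulus_set("categorization")


@pytest.fixture(scope="session")
def ident_set():
    return build_stimulus_set("identification")


@pytest.fixture(scope="session")
def interleaved_set():
    return build_stimulus_set("interleaved")


@pytest.fixture(scope="session")
def ddm_cat_trials(cat_set):
    """Fixed-policy constant-bound categorization session (fast batch path)."""
    return simulate_session(cat_set, Agent(), 20000, seed=2024)


@pytest.fixture(scope="session")
def bayes_cat_trials(cat_set):
    """Bayes-DDM categorization session with the default study conditions."""
    spec = make_model("bayes")
    return spec.simulate(spec.defaults, cat_set, 20000, 77)


@pytest.fixture(scope="session")
def bayes_ident_trials(ident_set):
    spec = make_model("bayes")
    return spec.simulate(spec.defaults, ident_set, 20000, 78)
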