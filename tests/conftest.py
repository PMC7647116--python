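"""Shared fixtures: a small simulated cohort and fitted posteriors.

Expensive MCMC fits are session-scoped so several tests can interrogate the
same posterior.  Convergence warnings from deliberately short test chains
are silenced at the fixture level; the tests assert on posterior content,
not on the convergence flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from puckslide.physics import EnvironmentParams
from puckslide.synthetic import ProfileDistributions, make_cohort, simulate_cohort
from puckslide.interaction import InteractionModelSpec, MCMCSettings, fit


@pytest.fixture(scope="session")
def env():
    return EnvironmentParams()


@pytest.fixture(scope="session")
def small_cohort(env):
    """Two newtonian/quadratic subjects with all four phases simulated."""
    profiles = make_cohort(2, seed=5)
    trials, collisions = simulate_cohort(profiles, env)
    return profiles, trials, collisions


@pytest.fixture(scope="session")
def feedback_trials(small_cohort):
    _, trials, _ = small_cohort
    return trials[trials["phase"] == "feedback"]


def _short_spec(**kw):
    kw.setdefault("mcmc", MCMCSettings(chains=2, warmup=200, draws=300, seed=3))
    return InteractionModelSpec(**kw)


@pytest.fixture(scope="session")
def newtonian_fit(feedback_trials):
    spec = _short_spec(model_class="newtonian", cost_function="quadratic")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit(feedback_trials, spec)
    return spec, post


@pytest.fixture(scope="session")
def linear_fit(feedback_trials):
    spec = _short_spec(model_class="linear", cost_function="quadratic")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit(feedback_trials, spec)
    return spec, post
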