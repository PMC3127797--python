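"""Shared fixtures.

The heavy session-scoped fixtures run the study's ensembles once at the
acceptance scale (K=100 initializations, M=200 second-session trials, fixed
study seed) and are shared by every test that needs them.
"""

from __future__ import annotations

import numpy as np
import pytest

import netscape as ns
from netscape.protocol import representative_state


@pytest.fixture(scope="session")
def suite():
    return ns.builtin_suite(12)


@pytest.fixture(scope="session")
def fan(suite):
    return suite[0]


@pytest.fixture(scope="session")
def stacked(suite):
    return suite[-1]


@pytest.fixture(scope="session")
def D_o():
    return ns.generate_original_points()


@pytest.fixture(scope="session")
def exp_config():
    return ns.ExperimentConfig()


@pytest.fixture(scope="session")
def unlimited_ensembles(suite, D_o, exp_config):
    """K=100 unlimited-budget first-session censuses, one per architecture."""
    return {spec.name: ns.run_initialization_ensemble(
                spec, D_o, 100, "unlimited", ns.STUDY_SEED, exp_config)
            for spec in suite}


@pytest.fixture(scope="session")
def limited_ensembles(suite, D_o, exp_config):
    """K=100 limited-budget (T=500) first-session censuses."""
    return {spec.name: ns.run_initialization_ensemble(
                spec, D_o, 100, "limited", ns.STUDY_SEED, exp_config)
            for spec in suite}


@pytest.fixture(scope="session")
def trial_ensembles(suite, D_o, exp_config, unlimited_ensembles):
    """M=200 second-session trials per architecture, each starting from the
    sampled state whose first-session error is representative of the
    unlimited-ensemble average."""
    out = {}
    for spec in suite:
        s1 = representative_state(unlimited_ensembles[spec.name], D_o)
        out[spec.name] = (s1, ns.run_trial_ensemble(spec, s1, D_o, exp_config,
                                                    n_trials=200))
    return out


@pytest.fixture(scope="session")
def fan_zero_fit(fan, D_o):
    """A zero-error fan minimum (deterministic seed)."""
    trace = ns.train_network(fan, ns.initialize_weights(fan, 42), D_o)
    assert trace.final_error < 1e-12
    return trace
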