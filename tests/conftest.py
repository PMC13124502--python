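"""Shared fixtures.

The full default experiment (20 participants, 360 two-minute trials) is
generated and feature-extracted once per session and reused by every test
that needs realistic data at study scale; smaller fixtures cover the
cheap unit tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from emofuse.pipeline import extract_feature_tables
from emofuse.synth import SynthConfig, default_profiles, generate_experiment


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def default_trials():
    """The full default synthetic experiment (360 trials)."""
    return generate_experiment(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def default_tables(default_trials):
    """Feature tables extracted from the default experiment."""
    trial_table, window_table, log = extract_feature_tables(default_trials)
    return trial_table, window_table, log


@pytest.fixture(scope="session")
def small_tables():
    """A small (4-participant) experiment for faster integration tests."""
    trials = generate_experiment(SynthConfig(n_participants=4, seed=23))
    trial_table, window_table, log = extract_feature_tables(trials)
    return trial_table, window_table, log


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
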