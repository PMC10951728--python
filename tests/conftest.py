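"""Shared fixtures: synthetic trials are generated once per session."""

import numpy as np
import pytest

from hopexo.hopper import ExoConfig, HopperParams, simulate_trial
from hopexo.pipeline import analyze_trial
from hopexo.springs import profile_for_condition

JOINTS = ("ankle", "knee", "hip")


@pytest.fixture(scope="session")
def nh_trial():
    return simulate_trial(HopperParams(n_hops=10, seed=3))


@pytest.fixture(scope="session")
def dg_trial():
    profile = profile_for_condition("DG", 66.0)
    return simulate_trial(
        HopperParams(n_hops=10, seed=3, exo=ExoConfig(profile=profile))
    )


@pytest.fixture(scope="session")
def nh_result(nh_trial):
    return analyze_trial(nh_trial[0])


@pytest.fixture(scope="session")
def dg_result(dg_trial):
    return analyze_trial(dg_trial[0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
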