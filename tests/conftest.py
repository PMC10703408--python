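import numpy as np
import pytest
from hypothesis import settings

import reachsel as rs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pooled_reach():
    return rs.POOLED_REACH_PARAMS


@pytest.fixture(scope="session")
def pooled_selection():
    return rs.POOLED_SELECTION_PARAMS


@pytest.fixture(scope="session")
def exp1_session(pooled_reach, pooled_selection):
    """One Experiment 1 session (40 deg bias) simulated at pooled parameters."""
    config = rs.TaskConfig.experiment1(40.0)
    return rs.run_session(pooled_reach, pooled_selection, config, seed=11)


@pytest.fixture(scope="session")
def exp2_session(pooled_reach, pooled_selection):
    config = rs.TaskConfig.experiment2()
    return rs.run_session(pooled_reach, pooled_selection, config, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
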