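import numpy as np
import pytest

from betawheel import evaluation, synthdata
from betawheel.config import KinematicsConfig, TaskConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_tasks():
    return [TaskConfig(condition="predictable", n_trials_per_block=6, n_blocks=1),
            TaskConfig(condition="unpredictable", n_trials_per_block=6, n_blocks=1)]


@pytest.fixture(scope="session")
def small_subject(small_tasks):
    """One small synthetic subject reused by read-only tests."""
    rng = np.random.default_rng(777)
    return synthdata.simulate_subject(
        "sub-00", small_tasks, KinematicsConfig(),
        synthdata.default_channel_specs(), synthdata.default_coupling_specs(), rng)


@pytest.fixture(scope="session")
def stationary_epochs():
    """Stationary beta-oscillation epochs (no event modulation), 30 trials."""
    data, names = synthdata.simulate_epochs(
        30, [evaluation.stationary_channel("STN_contra"),
             evaluation.stationary_channel("M1_contra")],
        seed=4242)
    return evaluation.epochs_from_array(data, names=names)
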