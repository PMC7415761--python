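import numpy as np
import pytest

from canishow import SimConfig, build_observation_table, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full simulated study (30 pairs) shared across tests."""
    logs, contexts, truth = simulate_dataset(SimConfig(seed=20260920))
    return logs, contexts, truth


@pytest.fixture(scope="session")
def default_observations(default_dataset):
    logs, contexts, truth = default_dataset
    obs, cells = build_observation_table(logs)
    return obs, cells


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
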