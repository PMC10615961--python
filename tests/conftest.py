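import numpy as np
import pytest

from surgilearn.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A compact study: 8 participants, 16 channels, 8 s recordings."""
    return SimulationConfig(
        n_participants=8,
        n_attempts=5,
        eeg_channels=16,
        duration=8.0,
        louvain_runs=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """(feature_table, ground_truth, cohort) of the compact study."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(small_config)
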