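import numpy as np
import pytest

import dtsleep as d


@pytest.fixture(scope="session")
def oxmc_config():
    """Dual-ablated dark-phase preset, 3 h (enough for dozens of DT bouts)."""
    return d.preset_config("OXMC_ablated", "dark", duration=3 * 3600.0, seed=0)


@pytest.fixture(scope="session")
def oxmc_truth(oxmc_config):
    return d.simulate_hypnogram(oxmc_config)


@pytest.fixture(scope="session")
def oxmc_recording(oxmc_truth):
    return d.synthesize_signals(oxmc_truth)


@pytest.fixture(scope="session")
def oxmc_scored(oxmc_recording):
    return d.score_recording(oxmc_recording)


@pytest.fixture(scope="session")
def oxmc_features(oxmc_scored):
    return oxmc_scored.features


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
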