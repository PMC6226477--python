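import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from g4rp.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced study for unit tests: same design, fewer/shorter transcripts."""
    return SimulationConfig(n_transcripts=250, length_range=(400, 1200), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(records, counts matrix, truth) for the reduced study."""
    return simulate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20180913)
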