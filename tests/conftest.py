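import pathlib
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from ancdelivery.simulate import SimulationConfig, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

FIXTURE_DIR = pathlib.Path(__file__).resolve().parents[1] / "fixtures"
FIXTURE_CSV = FIXTURE_DIR / "anc_synthetic_n500.csv"
FIXTURE_SEED = 1729


@pytest.fixture(scope="session")
def fixture_path():
    return FIXTURE_CSV


@pytest.fixture(scope="session")
def fixture_config():
    return replace(SimulationConfig(), n=500, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def medium_dataset():
    """One moderately sized draw under the default (rho=-0.4) conditions."""
    config = replace(SimulationConfig(), n=20_000, seed=7)
    return generate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
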