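import warnings

import numpy as np
import pytest

import circmilink as cm
from circmilink.model import DNNConfig, HopeConfig, PipelineConfig, SAEConfig

warnings.filterwarnings("ignore", message="hidden_dim.*no compression")


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale planted study for unit tests (kept small for speed)."""
    return cm.generate_study(
        cm.StudyConfig(n_circ=60, n_mi=30, n_blocks=3, seed=7)
    )


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline config with short trainings for contract-level tests."""
    return PipelineConfig(
        sae=SAEConfig(hidden_dim=16, epochs=5),
        dnn=DNNConfig(hidden_layers=(32, 16), max_epochs=8, patience=3),
        hope=HopeConfig(beta=8),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
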