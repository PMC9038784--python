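import numpy as np
import pytest

from dielflux import ExperimentDesign, IrradianceProfile
from dielflux.model import SimConfig


@pytest.fixture
def design():
    return ExperimentDesign()


@pytest.fixture
def light():
    return IrradianceProfile()


@pytest.fixture
def sim_config():
    return SimConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
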