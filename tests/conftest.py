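import numpy as np
import pytest

from visrsim.config import StudyConfig
from visrsim.materials import material_library
from visrsim.study import push_sequence_from_config


@pytest.fixture(scope="session")
def cfg():
    return StudyConfig()


@pytest.fixture(scope="session")
def seq(cfg):
    return push_sequence_from_config(cfg)


@pytest.fixture(scope="session")
def panel():
    return material_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
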