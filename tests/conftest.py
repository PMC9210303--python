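import numpy as np
import pytest

from peakforge.simulate import (
    SimulationConfig,
    make_annotation,
    make_design_table,
)


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def genome(config):
    return make_annotation(config)


@pytest.fixture(scope="session")
def design(config):
    return make_design_table(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
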