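import numpy as np
import pytest

from bgdbs.params import NEURON_PARAMS, STP_CLASSES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stn():
    return NEURON_PARAMS["STN"]


@pytest.fixture
def gpe_ti():
    return NEURON_PARAMS["GPe_TI"]


@pytest.fixture
def d1():
    return NEURON_PARAMS["D1"]


@pytest.fixture
def fsn():
    return NEURON_PARAMS["FSN"]


@pytest.fixture
def stp_classes():
    return STP_CLASSES


def tiny_sizes(**overrides):
    """All-zero population sizes except the requested ones."""
    sizes = {k: 0 for k in
             ("D1", "D2", "FSN", "GPe_TA", "GPe_TI", "STN")}
    sizes.update(overrides)
    return sizes
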