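import numpy as np
import pytest

from calbold import GasConstants, SimulationConfig, make_paradigm


@pytest.fixture(scope="session")
def constants():
    return GasConstants()


@pytest.fixture(scope="session")
def paradigm_a():
    return make_paradigm("A", tr=2.4)


@pytest.fixture(scope="session")
def paradigm_b():
    return make_paradigm("B", tr=2.4)


@pytest.fixture
def noiseless_config():
    return SimulationConfig(tsnr=np.inf, n_reps=2, seed=0)
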