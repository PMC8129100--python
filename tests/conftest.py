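import numpy as np
import pytest

from neuroaggsim import model_core as mc
from neuroaggsim import simulator as sim


@pytest.fixture(scope="session")
def optimized_params():
    params, schedule = mc.get_preset("optimized")
    return params, schedule


@pytest.fixture(scope="session")
def small_slit_config():
    """A short slit small enough for fast unit-level runs."""
    conf = sim.Confinement(kind="slit", length=600.0, width=200.0, height=100.0)
    return sim.SimulationConfig(confinement=conf, seed=7)


@pytest.fixture(scope="session")
def small_trajectory(small_slit_config):
    """One completed small-slit run shared by morphometric tests."""
    return sim.run(small_slit_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
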