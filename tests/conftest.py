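import numpy as np
import pytest

from clock3.integrators import SimulationConfig
from clock3.network import ParameterSet, build_network
from clock3.toy import ToyParams, build_toy_network


@pytest.fixture(scope="session")
def clock_network():
    return build_network()


@pytest.fixture(scope="session")
def toy_network():
    return build_toy_network()


@pytest.fixture(scope="session")
def toy_params():
    return ToyParams()


@pytest.fixture(scope="session")
def default_params():
    return ParameterSet.defaults()


@pytest.fixture(scope="session")
def fitted_ensemble():
    from clock3.fixtures import load_fitted_ensemble
    return load_fitted_ensemble()


@pytest.fixture(scope="session")
def fast_config():
    """Short feature window used where full 600 h runs are unnecessary."""
    return SimulationConfig(dt=0.005, t_end=300.0, transient_discard=180.0,
                            sample_every=10)


@pytest.fixture(scope="session")
def standard_config():
    return SimulationConfig(dt=0.005, t_end=600.0, transient_discard=360.0,
                            sample_every=20)


@pytest.fixture(scope="session")
def toy_config():
    return SimulationConfig(dt=0.005, t_end=500.0, transient_discard=250.0,
                            sample_every=20)


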