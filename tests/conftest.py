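import numpy as np
import pytest

from thalcort.model import ModelParameters
from thalcort.simulate import SimulationConfig, cortical_mean, integrate


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def swd_cortical_mean():
    """Cortical mean of the reference spike-wave run (C7=2, C11=0.1)."""
    res = integrate(SimulationConfig(params=ModelParameters(C7=2.0, C11=0.1)))
    return cortical_mean(res)


@pytest.fixture(scope="session")
def decoupled_params():
    """All couplings and inputs zero: five independent leak equations."""
    zeros = {f"C{i}": 0.0 for i in range(1, 13)}
    zeros.update(Cin1=0.0, Cin2=0.0, Ciny=0.0,
                 hPY=0.0, hI1=0.0, hI2=0.0, hTC=0.0, hRE=0.0)
    return ModelParameters(**zeros)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
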