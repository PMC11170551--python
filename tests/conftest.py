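import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exqnmr import spinsim
from exqnmr.attenuation import RelaxationParams

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def doublet_system():
    """One active spin at offset 0 coupled to one passive spin, J = 10 Hz."""
    spins = [
        spinsim.Spin("a", 0.0, "active", RelaxationParams(T1=60.0, T2=60.0)),
        spinsim.Spin("p", 400.0, "passive"),
    ]
    J = np.array([[0.0, 10.0], [10.0, 0.0]])
    return spinsim.SpinSystem(spins=spins, J=J, amplitudes={"a": 1.0})


@pytest.fixture
def singlet_system():
    spins = [spinsim.Spin("s", 0.0, "active", RelaxationParams(T1=60.0, T2=60.0))]
    return spinsim.SpinSystem(spins=spins, J=np.zeros((1, 1)), amplitudes={"s": 1.0})


@pytest.fixture
def chunked_scheme():
    """Interferogram scheme: tau = 20 ms, dwell 0.5 ms, 100 chunks."""
    return spinsim.AcquisitionScheme(
        mode="interferogram", dwell=5e-4, points=4000, tau=0.02, n_chunks=100
    )
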