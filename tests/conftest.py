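import numpy as np
import pytest

from oscidisk import Geometry, SimulationConfig


@pytest.fixture(scope="session")
def ref_config() -> SimulationConfig:
    """Reference parameter set (N=200, k_n=500, v_f=3.3, D=2.8)."""
    return SimulationConfig()

@pytest.fixture(scope="session")
def ref_geometry(ref_config) -> Geometry:
    return Geometry.from_config(ref_config)


@pytest.fixture()
def tiny_config() -> SimulationConfig:
    """A few particles in a short box; entire runs take well under a second."""
    return SimulationConfig(N=8, box_height=20.0,
                            reinjection_y_range=(14.0, 20.0),
                            T=2.0, seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
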