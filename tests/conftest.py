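import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

import mnpheat as mh


@pytest.fixture(scope="session")
def params():
    """Reference parameters: 5 nm radius, 320 K, water-like viscosity."""
    return mh.SimulationParams()


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(12345))


@pytest.fixture(scope="session")
def contact_lattice():
    """10x10 lattice at contact density for 5 nm particles (d = 10 nm)."""
    return mh.build_square_lattice(10, 10e-9, particle_radius=5e-9)


@pytest.fixture(scope="session")
def free_lattice():
    """16 lattice sites used with interactions disabled (the rho = 0 case)."""
    return mh.build_square_lattice(4, 1.0)
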