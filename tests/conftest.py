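import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ensemblefit.maps import SpreadConfig
from ensemblefit.synth import ToySystemConfig, make_helix, make_kinked_helix, make_toy_system


@pytest.fixture(scope="session")
def helix20():
    return make_helix(20)


@pytest.fixture(scope="session")
def helix40():
    return make_helix(40)


@pytest.fixture(scope="session")
def kinked40():
    return make_kinked_helix(40, 20, 40.0)


@pytest.fixture(scope="session")
def small_system():
    """Reduced two-state system for fast unit tests (not the study defaults)."""
    return make_toy_system(ToySystemConfig(n_res=20, kink_residue=10,
                                           ensemble_size=30, seed=7))


@pytest.fixture(scope="session")
def default_system():
    """The default study conditions (full-size toy system)."""
    return make_toy_system(ToySystemConfig(seed=0))


@pytest.fixture(scope="session")
def spread15():
    return SpreadConfig(sigma=1.5)


def random_rotation(rng):
    """Uniform random proper rotation matrix (for invariance tests)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
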