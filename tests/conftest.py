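import numpy as np
import pytest

from patellasim.geometry import KneeGeometryConfig, build_knee_mesh


@pytest.fixture(scope="session")
def default_config():
    return KneeGeometryConfig()


@pytest.fixture(scope="session")
def default_mesh(default_config):
    return build_knee_mesh(default_config)


@pytest.fixture(scope="session")
def coarse_config():
    """Small knee mesh for fast elasticity tests."""
    return KneeGeometryConfig(n_through_thickness=4, n_along_length=40)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_config):
    return build_knee_mesh(coarse_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
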