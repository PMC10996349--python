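import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tdcsflow as tf

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: coarse grid for fast unit/property solves (same voxel, ~6 um spacing)
COARSE_GRID = (24, 26, 70)
#: mid grid used where moderate accuracy matters
MID_GRID = (32, 36, 96)


@pytest.fixture(scope="session")
def default_params():
    return tf.DoubleLayerParams()


@pytest.fixture(scope="session")
def default_tj():
    return tf.TJGeometry()


@pytest.fixture(scope="session")
def network():
    """Synthetic capillary network at the in vivo length density."""
    return tf.generate_network(seed=1)


@pytest.fixture(scope="session")
def closed_1000(network):
    return tf.solve_voxel_current(
        network, "closed", 1000.0, 0.082, grid_shape=MID_GRID
    )


@pytest.fixture(scope="session")
def open_1000(network):
    return tf.solve_voxel_current(network, "open", 1000.0, 0.082, grid_shape=MID_GRID)


@pytest.fixture(scope="session")
def closed_5000(network):
    return tf.solve_voxel_current(
        network, "closed", 5000.0, 0.082, grid_shape=MID_GRID
    )


@pytest.fixture(scope="session")
def voxel_volume(network):
    return float(np.prod(network.voxel_dims))
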