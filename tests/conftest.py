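import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucshell import SimulationConfig, equal_volume_shells, simulate_nucleus
from nucshell.config import stage_rng
from nucshell.imaging import NucleusMask

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_sphere_mask(radius_um: float = 5.0, spacing=(0.2, 0.2, 0.2)) -> NucleusMask:
    """Digital sphere: voxel centers within radius of the grid center."""
    spacing = np.asarray(spacing, float)
    shape = tuple(int(np.ceil(2 * radius_um / s)) + 5 for s in spacing)
    center = (np.array(shape) - 1) / 2 * spacing
    idx = np.indices(shape)
    r = np.linalg.norm(np.stack(idx, -1) * spacing - center, axis=-1)
    return NucleusMask(1, r <= radius_um, tuple(spacing))


@pytest.fixture(scope="session")
def sphere_mask() -> NucleusMask:
    return make_sphere_mask()


@pytest.fixture(scope="session")
def sphere_partition(sphere_mask):
    return equal_volume_shells(sphere_mask, k=5, mode="edt")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def myoblast_nucleus(default_config):
    """One voxelized myoblast-like nucleus with its ground truth."""
    rng = stage_rng(default_config.seed, "fixture/myoblast")
    return simulate_nucleus(default_config, "myoblast", rng)
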