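import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leadspect.phantoms import PhantomSpec, VoxelGrid, build_voi_set

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def grid_for(spec: PhantomSpec, voxel_mm: float, margin_mm: float = 10.0) -> VoxelGrid:
    half = spec.bounding_half_extent_mm()
    return VoxelGrid.centered(tuple(h + margin_mm for h in half), voxel_mm)


@pytest.fixture(scope="session")
def nema_grid() -> VoxelGrid:
    """Reconstruction-resolution grid (2.4 mm) covering the NEMA IQ phantom."""
    return grid_for(PhantomSpec.nema_iq(1.0), 2.4)


@pytest.fixture(scope="session")
def nema_vois(nema_grid):
    """VOI scheme on the 2.4 mm grid; expensive, shared across tests."""
    return build_voi_set(PhantomSpec.nema_iq(1.0), nema_grid)


@pytest.fixture(scope="session")
def coarse_grid() -> VoxelGrid:
    """Coarse (4.8 mm) NEMA grid for statistics-heavy simulations."""
    return grid_for(PhantomSpec.nema_iq(1.0), 4.8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
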