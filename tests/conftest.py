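import numpy as np
import pytest

from alphamicro import (
    ShapeParams,
    VoxelTarget,
    WellLayout,
    alpha_range_energy_water,
    generate_cell_geometry,
    pb212_chain,
)


@pytest.fixture(scope="session")
def range_model():
    return alpha_range_energy_water()


@pytest.fixture(scope="session")
def decay_scheme():
    return pb212_chain()


@pytest.fixture(scope="session")
def coarse_layout():
    """Desk-scale grid: isotropic 0.4 µm voxels keep masks small in tests."""
    return WellLayout(width=150.0, height=150.0, voxel_size=(0.4, 0.4, 0.4))


@pytest.fixture(scope="session")
def confocal_layout():
    return WellLayout(width=150.0, height=150.0)


@pytest.fixture(scope="session")
def cell(coarse_layout):
    """One representative cell with derived compartments."""
    return generate_cell_geometry(
        (75.0, 75.0), ShapeParams(), coarse_layout, rng=7
    )


def voxel_sphere(radius_um: float, voxel_um: float) -> VoxelTarget:
    """Voxelized sphere centered at the world origin (shared test helper)."""
    n = 2 * int(np.ceil(radius_um / voxel_um)) + 3
    c = (n - 1) / 2.0
    ax = (np.arange(n) - c) * voxel_um
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = x * x + y * y + z * z <= radius_um**2
    return VoxelTarget(
        mask=mask,
        origin=np.array([-c * voxel_um] * 3),
        voxel_size=np.array([voxel_um] * 3),
    )


@pytest.fixture(scope="session")
def sphere_target():
    return voxel_sphere(5.0, 0.15)
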