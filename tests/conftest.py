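"""Shared fixtures: tissue table, small phantoms, and a miniature focused
bowl that fits fast test domains."""

import numpy as np
import pytest

from sonouq.acoustics import MaterialFields, SimulationConfig, TransducerSpec, VoxelSource
from sonouq.phantom import PhantomSpec, make_layered_phantom
from sonouq.tissuedb import default_tissue_table


@pytest.fixture(scope="session")
def table():
    return default_tissue_table()


@pytest.fixture
def water_column():
    """1D free-water column at the reference 0.5 mm spacing."""
    n = 240
    return MaterialFields(
        np.full((n,), 1000.0), np.full((n,), 1500.0), np.zeros(n), 0.5
    )


@pytest.fixture
def end_source():
    """Hard plane source at one end of a 1D column."""
    return VoxelSource(
        (np.array([2], dtype=np.int64),), np.array([1.0]), np.array([0.0]), 250e3
    )


@pytest.fixture
def mini_bowl():
    """Small focused bowl (16 mm radius of curvature) for fast 3D runs."""
    return TransducerSpec(
        radius_of_curvature_mm=16.0,
        aperture_diameter_mm=16.0,
        face_center_mm=(14.0, 14.0, 2.0),
    )


@pytest.fixture
def mini_domain_shape():
    return (28, 28, 44)


@pytest.fixture
def fast_config():
    """Desk-resolution solver settings (1 mm, 6 points per wavelength)."""
    return SimulationConfig(n_periods=30, points_per_wavelength=6)


@pytest.fixture(scope="session")
def tiny_phantom(table):
    """Three-slab phantom small enough for per-test simulations."""
    spec = PhantomSpec(
        grid_shape=(28, 28, 44),
        voxel_spacing_mm=1.0,
        layers=[("water", 8.0), ("skin", 3.0), ("skull", 5.0)],
        target=("amygdala", (14.0, 14.0, 24.0), 5.0),
    )
    return make_layered_phantom(spec, table)
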