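"""Shared fixtures: materials, grids, and cached forward simulations."""

import numpy as np
import pytest

from tfm25 import (DEFAULT_MATERIAL, ElasticMaterial, GridSpec,
                   centered_volume_grid, displacement_from_pattern,
                   preset_pattern)


@pytest.fixture(scope="session")
def material():
    """Compressible test material: keeps the direct method's dilatational
    term mild so scheme behaviour is visible over it."""
    return ElasticMaterial(youngs_modulus=1.0e4, poisson_ratio=0.3)


@pytest.fixture(scope="session")
def default_material():
    return DEFAULT_MATERIAL


@pytest.fixture(scope="session")
def indenter_volume():
    """Noiseless displacement volume of the standard indenter preset on the
    design grid (64 x 64 x 9 at 0.4 um), shared across tests."""
    grid = centered_volume_grid(64, 64, 9, 0.4)
    pattern = preset_pattern("indenter")
    u = displacement_from_pattern(pattern, grid, DEFAULT_MATERIAL)
    return pattern, u


@pytest.fixture
def small_volume_grid():
    return GridSpec(nx=8, ny=7, dx=0.5, dy=0.5, nz=6, dz=0.8,
                    origin=(0.0, 0.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
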