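import numpy as np
import pytest

from scaffoldregen import (
    SimulationConfig,
    make_design,
    material_field_for_grid,
    voxelize_design,
)


@pytest.fixture(scope="session")
def design_best():
    """Best-regenerating design of the study."""
    return make_design(0.7, 0.8)


@pytest.fixture(scope="session")
def design_screen_winner():
    """Design with the highest day-0 bone-favouring fraction."""
    return make_design(0.5, 0.9)


@pytest.fixture(scope="session")
def design_square():
    """Equal pores; representable even on coarse test grids."""
    return make_design(0.5, 0.5)


@pytest.fixture(scope="session")
def coarse_grid(design_square):
    """A small (10^3) voxelization for fast FE tests."""
    return voxelize_design(design_square, element_size=0.3)


@pytest.fixture(scope="session")
def coarse_materials(coarse_grid):
    return material_field_for_grid(coarse_grid)


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down run configuration for quick coupled simulations:
    0.3 mm elements (10^3 grid), 3 sites/element (0.1 mm agent lattice)."""
    return SimulationConfig(element_size=0.3, sites_per_element=3, days=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
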