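import numpy as np
import pytest

from invadescape import habitat
from invadescape.landscapes import LandscapeConfig, LandscapeRaster, \
    generate_landscape
from invadescape.simulate import HabitatParams


@pytest.fixture
def uniform_grass():
    return LandscapeRaster(np.full((12, 12), habitat.GRASSLAND))


@pytest.fixture
def checkerboard():
    grid = np.indices((8, 8)).sum(axis=0) % 2
    grid = np.where(grid == 0, habitat.GRASSLAND, habitat.CROP)
    return LandscapeRaster(grid.astype(np.int16))


@pytest.fixture
def half_and_half():
    grid = np.full((10, 10), habitat.GRASSLAND)
    grid[5:, :] = habitat.CROP
    return LandscapeRaster(grid.astype(np.int16))


@pytest.fixture
def mixed_raster():
    """A seeded 32x32 landscape with a moderate grassland share, some crop,
    barriers, and one road — the shared arena for simulator tests."""
    config = LandscapeConfig(
        target_proportions={"grassland": 0.4, "crop": 0.25, "pasture": 0.15,
                            "unsuitable": 0.12, "water": 0.03,
                            "deciduous forest": 0.05},
        fragmentation=0.5, n_rows=32, n_cols=32, n_roads=1, seed=11,
    )
    return generate_landscape(config)


@pytest.fixture
def params():
    return HabitatParams()
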