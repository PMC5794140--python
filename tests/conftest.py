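import numpy as np
import pytest

from sepmap.grid import GridGeometry, Raster
from sepmap.landscape import (
    LayoutConfig,
    SpectralSignatureModel,
    generate_landscape,
)


@pytest.fixture(scope="session")
def small_landscape():
    """A 120x120 synthetic landscape shared by read-only tests."""
    layout = LayoutConfig(shape=(120, 120), n_villages=4)
    return generate_landscape(SpectralSignatureModel(), layout, seed=7)


@pytest.fixture
def small_grid():
    return GridGeometry(
        origin_x=0.0, origin_y=3000.0, pixel_size=30.0, shape=(100, 100)
    )


@pytest.fixture
def uniform_raster(small_grid):
    def make(value, dtype=float, nodata=None):
        return Raster(
            np.full(small_grid.shape, value, dtype=dtype), small_grid, nodata
        )

    return make
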