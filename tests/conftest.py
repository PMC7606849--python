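import numpy as np
import pytest

from uavcanopy.geometry import GridGeometry
from uavcanopy.gridding import ElevationGrid
from uavcanopy.synthetic import generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_layout():
    """10 genotypes x 2 treatments x 2 reps = 40 plants."""
    return generate_field(10, 2, 2.5, seed=7)


def make_grid(values, cell_size=0.01, origin=(0.0, 0.0), role="CHM"):
    values = np.asarray(values, dtype=float)
    geom = GridGeometry(cell_size, origin, values.shape)
    return ElevationGrid(values, geom, role=role)


def disk_mask(radius_cells: int, pad: int = 5):
    """Boolean filled disk and the (row, col) of its center."""
    n = 2 * (radius_cells + pad) + 1
    c = radius_cells + pad
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius_cells**2, (c, c)
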