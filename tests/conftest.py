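import numpy as np
import pytest

from isoprov.raster import GridTransform, RasterGrid
from isoprov.synthetic import make_landscape, sample_training_points, simulate_individuals


@pytest.fixture(scope="session")
def small_truth():
    """A compact landscape reused across module tests."""
    return make_landscape(seed=11, n_rows=40, n_cols=40, n_geo_units=4, sr_noise_sd=0.002)


@pytest.fixture(scope="session")
def small_training(small_truth):
    return sample_training_points(small_truth, 200, 0.002, seed=12)


@pytest.fixture(scope="session")
def small_individuals(small_truth):
    return simulate_individuals(
        small_truth, 120, 0.15, 2 * small_truth.correlation_length_km, seed=13
    )


def toy_raster(values, x0=10.0, y0=60.0, cell=0.1):
    """Tiny raster helper for hand-computed oracles."""
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, GridTransform(x0=x0, y0=y0, dx=cell, dy=-cell))


@pytest.fixture
def constant_raster():
    return toy_raster(np.full((8, 8), 0.715))
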