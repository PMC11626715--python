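import numpy as np
import pandas as pd
import pytest

from isomigrate import synthetic
from isomigrate.grid import GeoGrid, GridSpec


@pytest.fixture(scope="session")
def standard_world():
    """The standard synthetic test world (seed 1)."""
    return synthetic.make_standard_world(1)


@pytest.fixture(scope="session")
def training_points(standard_world):
    noise = synthetic.NoiseSpec(seed=1)
    return synthetic.sample_training_points(
        standard_world.sr_isoscape, 500, noise, seed=11)


@pytest.fixture(scope="session")
def fitted_model(standard_world, training_points):
    """A fitted ensemble on the standard world, shared across tests."""
    from isomigrate import eml
    return eml.fit_ensemble(training_points, standard_world.predictor_stack,
                            seed=1)


def toy_grid(probs, cell=1.0, crs="cartesian", x0=0.0, y0=0.0):
    """A GeoGrid from a nested list (NaN = nodata)."""
    arr = np.asarray(probs, dtype=float)
    spec = GridSpec(arr.shape[0], arr.shape[1], x0, y0, cell, crs)
    return GeoGrid(arr, spec)


@pytest.fixture
def three_cell_posterior():
    """1x3 cartesian grid with probabilities (0.5, 0.3, 0.2)."""
    from isomigrate.assignment import PosteriorSurface
    return PosteriorSurface(toy_grid([[0.5, 0.3, 0.2]]))
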