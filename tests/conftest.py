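import numpy as np
import pytest

from lesionconn import phantoms


@pytest.fixture(scope="session")
def fig2_lesioned():
    """Canonical crossing phantom with the focal lesion (0.14 -> 0.07)."""
    return phantoms.make_fig2_phantom(lesion=True)


@pytest.fixture(scope="session")
def fig2_healthy():
    return phantoms.make_fig2_phantom(lesion=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_polyline(rng, grid_shape, n_points=8, margin=0.25):
    """Random polyline strictly inside the grid (unit voxels)."""
    hi = np.asarray(grid_shape, dtype=float) - margin
    return rng.uniform(margin, hi, size=(n_points, 3))
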