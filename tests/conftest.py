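import numpy as np
import pytest

from atriasim import fixtures as fx
from atriasim import geometry as geo


@pytest.fixture(scope="session")
def sheet_coarse():
    """30 x 30 mm sheet at 600 µm — analysis-stage workhorse."""
    return geo.generate_sheet_mesh(30.0, 30.0, 600.0)


@pytest.fixture(scope="session")
def sheet_small():
    """10 x 10 mm sheet at 500 µm for cheap geometry checks."""
    return geo.generate_sheet_mesh(10.0, 10.0, 500.0)


@pytest.fixture(scope="session")
def sphere_mesh():
    return geo.generate_sphere_mesh(10.0, subdivisions=3)


@pytest.fixture(scope="session")
def spiral_movie(sheet_coarse):
    """Stationary spiral movie plus ground-truth tip path."""
    return fx.make_spiral_movie(
        sheet_coarse, core=(15.0, 15.0), duration_ms=1500.0
    )


@pytest.fixture(scope="session")
def calibrated_kappas():
    """Conduction calibration at the reference mesh density (expensive)."""
    from atriasim.propagation import calibrate_conduction

    return calibrate_conduction()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
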