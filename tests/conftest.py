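import numpy as np
import pandas as pd
import pytest

from nichescreen.grid_io import EnvGrid, write_ascii_grid
from nichescreen.maxent_engine import ModelSettings
from nichescreen.synthetic_data import SyntheticScenario, make_screen_data


@pytest.fixture(scope="session")
def small_scenario():
    """A quick 6-layer scenario with 2 strong true variables."""
    return SyntheticScenario(
        grid_shape=(40, 40), n_layers=6, smoothness=4.0,
        cross_correlation=0.3,
        true_variables=("env01", "env03"),
        true_coefficients={"linear": {"env01": 2.0, "env03": -1.8}},
        n_presences=80, seed=42)


@pytest.fixture(scope="session")
def small_data(small_scenario):
    """ScreenData (presence/background tables), grid, and suitability."""
    return make_screen_data(small_scenario, n_background=400)


@pytest.fixture(scope="session")
def fast_settings():
    """Low-knot settings that keep many-fit tests quick."""
    return ModelSettings(hinge_knots=8, threshold_knots=8)


@pytest.fixture
def tiny_grid():
    """3-layer 10x10 grid: layer values 7, row index, column index."""
    const = np.full((10, 10), 7.0)
    rows = np.tile(np.arange(10.0)[:, None], (1, 10))
    cols = np.tile(np.arange(10.0)[None, :], (10, 1))
    mask = np.zeros((10, 10), dtype=bool)
    return EnvGrid(["const", "rowval", "colval"],
                   np.stack([const, rows, cols]), mask,
                   xllcorner=-100.0, yllcorner=30.0, cellsize=0.5)


@pytest.fixture
def asc_files(tmp_path):
    """Two aligned 10x10 single-band ASCII grids on disk; file B has one
    nodata cell at (row 2, col 3)."""
    a = np.arange(100, dtype=float).reshape(10, 10)
    b = np.ones((10, 10)) * 5.0
    mask_b = np.zeros((10, 10), dtype=bool)
    mask_b[2, 3] = True
    pa, pb = tmp_path / "layA.asc", tmp_path / "layB.asc"
    write_ascii_grid(pa, a, xllcorner=0.0, yllcorner=0.0, cellsize=1.0)
    write_ascii_grid(pb, b, xllcorner=0.0, yllcorner=0.0, cellsize=1.0,
                     nodata_mask=mask_b)
    return pa, pb, a, b, mask_b


@pytest.fixture
def separable_data():
    """One variable perfectly separates presences (high) from background."""
    rng = np.random.default_rng(7)
    pres = pd.DataFrame({"sig": rng.uniform(0.8, 1.0, 40),
                         "noise": rng.normal(size=40)})
    bg = pd.DataFrame({"sig": rng.uniform(0.0, 0.2, 300),
                       "noise": rng.normal(size=300)})
    return pres, bg
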