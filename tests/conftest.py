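import numpy as np
import pandas as pd
import pytest

from lagoshift.env_stack import EnvStack, GridSpec


@pytest.fixture
def grid():
    """10 x 12 cells of 0.5 deg starting at (0 E, 55 N)."""
    return GridSpec(n_rows=10, n_cols=12, cell_size=0.5, x_origin=0.0, y_origin=55.0)


@pytest.fixture
def stack(grid):
    rng = np.random.default_rng(42)
    lat = np.repeat(grid.row_latitudes()[:, None], grid.n_cols, axis=1)
    lon = np.repeat(grid.col_longitudes()[None, :], grid.n_rows, axis=0)
    return EnvStack(
        period_label="post1950",
        grid=grid,
        layers={
            "temp": 30.0 - lat + 0.1 * rng.standard_normal((grid.n_rows, grid.n_cols)),
            "precip": 100.0 + 10.0 * lon,
        },
    )


@pytest.fixture
def records():
    return pd.DataFrame(
        {
            "species": ["a", "a", "a", "b", "b"],
            "lon": [0.3, 1.3, 2.3, 3.3, 4.3],
            "lat": [54.8, 53.8, 52.8, 51.8, 50.8],
            "year": [1920, 1960, 1980, 2000, 1940],
            "precision_km": [1.0, 1.0, 1.0, 1.0, 1.0],
            "source": ["s1", "s2", "s3", "s4", "s5"],
        }
    )
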