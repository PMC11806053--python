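import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from benthocur import geo  # noqa: E402
from benthocur.synthgen import SurveyRecipe, gen_site  # noqa: E402


def metres_to_deg(lat0, east_m, north_m):
    dlat = np.asarray(north_m, float) / geo.METRES_PER_DEGREE
    dlon = np.asarray(east_m, float) / (geo.METRES_PER_DEGREE
                                        * np.cos(np.radians(lat0)))
    return dlat, dlon


def random_points(rng, n, lat0=44.5, lon0=-63.5, extent_m=2000.0):
    east = rng.uniform(0, extent_m, n)
    north = rng.uniform(0, extent_m, n)
    dlat, dlon = metres_to_deg(lat0, east, north)
    return lat0 + dlat, lon0 + dlon


@pytest.fixture
def unlabelled_table():
    """Small conforming unlabelled metadata table (three sites)."""
    frames = [
        gen_site(SurveyRecipe(kind="transect", n=8, spacing_m=1.0,
                              jitter_sd_m=0.0, site="t0", seed=1)),
        gen_site(SurveyRecipe(kind="stations", n=5, spacing_m=10.0,
                              site="s0", start_lon=-63.3, seed=2)),
        gen_site(SurveyRecipe(kind="unlocated", n=4, site="u0", seed=3)),
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def small_grid():
    """5x4 grid, 0.25 deg cells, values = 10*i + j, one masked cell."""
    vals = np.array([[10.0 * i + j for j in range(4)] for i in range(5)])
    mask = np.zeros_like(vals, dtype=bool)
    mask[2, 2] = True
    return geo.GeoGrid(origin_lat=40.0, origin_lon=-64.0, cell_size=0.25,
                       values=vals, mask=mask)
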