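"""Shared fixtures: small grids and constant forcing fields."""

import numpy as np
import pytest

from spillsim.environment import constant_fields
from spillsim.grids import GridSpec


@pytest.fixture
def small_grid():
    """Coarse 10x10-ish domain with a 10-day 3-hourly time axis."""
    return GridSpec(
        lat_min=12.0, lat_max=18.0, lon_min=39.0, lon_max=45.0, cell_size=0.5,
        t_start="2020-06-01", t_end="2020-06-30", t_step_h=3.0,
    )


@pytest.fixture
def still_water(small_grid):
    return constant_fields(small_grid, current=(0.0, 0.0), wind=(0.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
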