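"""Shared small-scale fixtures: an 8x8 world, one humid cell's forcing."""

from __future__ import annotations

import numpy as np
import pytest

from cryptoweather.climate import generate_monthly_climate
from cryptoweather.downscale import downscale_to_hourly
from cryptoweather.geography import generate_paleogeography
from cryptoweather.grid import make_grid
from cryptoweather.species import sample_species
from cryptoweather.vegetation import VegConfig

SEED = 2024


@pytest.fixture(scope="session")
def grid8():
    return make_grid(8, 8)


@pytest.fixture(scope="session")
def paleo8(grid8):
    return generate_paleogeography(grid8, seed=SEED)


@pytest.fixture(scope="session")
def climate8(paleo8):
    return generate_monthly_climate(paleo8, co2_pal=8.0, seed=SEED)


@pytest.fixture(scope="session")
def humid_cell(paleo8, climate8):
    """(i, j) of the rainiest land cell — a reliably vegetated column."""
    rain = np.nansum(climate8.rainfall, axis=0)
    land = np.argwhere(paleo8.land_mask)
    return max(map(tuple, land), key=lambda ij: rain[ij])


@pytest.fixture(scope="session")
def humid_forcing(paleo8, climate8, humid_cell):
    i, j = humid_cell
    lat = float(paleo8.grid.lat_centers[i])
    return downscale_to_hourly(climate8.cell(i, j), lat, seed=SEED)


@pytest.fixture(scope="session")
def species_pool():
    return sample_species(12, seed=SEED)


@pytest.fixture(scope="session")
def veg_cfg():
    return VegConfig(n_species=12, n_years=20)
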