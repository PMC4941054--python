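"""Build a synthetic Ordovician-style world: grid, continents, climate.

Prints the land fraction, the area-weighted mean land temperature at
8 PAL of CO2 (1 PAL = 280 ppm), and the zonal annual rainfall profile —
wet equator, dry subtropics — that drives everything downstream.
"""

import numpy as np

from cryptoweather import generate_monthly_climate, generate_paleogeography, make_grid
from cryptoweather.grid import area_weighted_mean

grid = make_grid(48, 24)
paleo = generate_paleogeography(grid, seed=1)
climate = generate_monthly_climate(paleo, co2_pal=8.0, seed=1)

t_land = area_weighted_mean(climate.air_temperature.mean(axis=0), grid, paleo.land_mask)
print(f"land fraction        : {paleo.land_fraction:.3f} of the globe")
print(f"mean land temperature: {t_land:.1f} degC at 8 PAL CO2")
print(f"elevation on land    : mean {paleo.elevation[paleo.land_mask].mean():.0f} m, "
      f"max {paleo.elevation.max():.0f} m")

annual_rain = (climate.rainfall + climate.snowfall).sum(axis=0).mean(axis=1)
print("\nzonal annual precipitation (mm/yr):")
for i in range(0, grid.n_lat, 3):
    bar = "#" * int(annual_rain[i] / 80)
    print(f"  {grid.lat_centers[i]:+6.1f}  {annual_rain[i]:7.0f}  {bar}")
print("\nThe equatorial maximum and ~30-degree minima mirror the Hadley"
      " circulation; land temperature shifts ~3 degC per CO2 doubling.")
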