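"""Synthetic paleogeography: land mask, elevation and glacier masks.

Emulates a Late-Ordovician-style configuration — a southern-hemisphere-
weighted supercontinent plus scattered low-latitude landmasses — without
reproducing any real reconstruction.  Land placement thresholds a smoothed
random field biased toward the southern mid-latitudes; elevation is a
smoothed nonnegative random field tapered toward the coasts so interiors are
high and coasts low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridSpec

SCENARIOS = ("baseline", "hirnantian_ice")

#: Latitude (deg) south of which the Hirnantian scenario prescribes ice.
HIRNANTIAN_ICE_LAT = -30.0


@dataclass(frozen=True)
class Paleogeography:
    grid: GridSpec
    land_mask: np.ndarray = field(repr=False)      # bool (n_lat, n_lon)
    elevation: np.ndarray = field(repr=False)      # m above sea level, 0 on ocean
    glacier_mask: np.ndarray = field(repr=False)   # bool, subset of land
    scenario_tag: str = "baseline"

    @property
    def land_fraction(self) -> float:
        a = self.grid.cell_area
        return float((a * self.land_mask).sum() / a.sum())


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean unit-variance smooth random field, periodic in longitude."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode=("nearest", "wrap"))
    sm -= sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_paleogeography(
    grid: GridSpec,
    seed: int,
    scenario: str = "baseline",
    land_fraction: float = 0.25,
    mean_elevation_m: float = 500.0,
    max_elevation_m: float = 3000.0,
) -> Paleogeography:
    """Generate a deterministic synthetic paleogeography.

    Parameters
    ----------
    seed
        Master seed; identical inputs give bit-identical output.
    scenario
        ``"baseline"`` (no prescribed ice) or ``"hirnantian_ice"``
        (glaciers prescribed on all land south of 30 deg S).
    land_fraction
        Target fraction of the globe (by area) covered by land.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if not 0.0 < land_fraction < 1.0:
        raise ValueError("land_fraction must be in (0, 1)")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    lat = grid.lat_field

    # Continent score: smooth noise plus a bias favouring a southern
    # supercontinent (centred near 45 S) and a weaker equatorial band.
    noise = _smooth_noise(rng, grid.shape, sigma=max(1.5, grid.n_lat / 12))
    bias = 1.6 * np.exp(-(((lat + 45.0) / 25.0) ** 2)) + 0.7 * np.exp(-((lat / 18.0) ** 2))
    score = noise + bias
    # Area-weighted threshold so the land fraction is met on the sphere.
    order = np.argsort(score.ravel())[::-1]
    areas = grid.cell_area.ravel()[order]
    cum = np.cumsum(areas) / areas.sum()
    n_land = int(np.searchsorted(cum, land_fraction)) + 1
    land = np.zeros(score.size, dtype=bool)
    land[order[:n_land]] = True
    land = land.reshape(grid.shape)

    # Elevation: nonnegative smooth field, tapered by distance-from-coast so
    # coasts are low and interiors high; normalised to the target land mean.
    relief = _smooth_noise(rng, grid.shape, sigma=max(1.0, grid.n_lat / 16))
    relief = (relief - relief.min()) + 0.1
    interior = ndimage.gaussian_filter(
        land.astype(float), sigma=max(1.0, grid.n_lat / 16), mode=("nearest", "wrap")
    )
    elevation = relief * interior
    elevation[~land] = 0.0
    if land.any() and elevation[land].mean() > 0:
        elevation *= mean_elevation_m / elevation[land].mean()
    np.clip(elevation, 0.0, max_elevation_m, out=elevation)
    elevation[~land] = 0.0

    glacier = np.zeros(grid.shape, dtype=bool)
    if scenario == "hirnantian_ice":
        glacier = land & (lat < HIRNANTIAN_ICE_LAT)

    return Paleogeography(
        grid=grid,
        land_mask=land,
        elevation=elevation,
        glacier_mask=glacier,
        scenario_tag=scenario,
    )
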