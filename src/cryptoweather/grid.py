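"""Regular latitude-longitude grids with spherical cell areas.

All gridded fields in this package live on a regular lat/lon grid whose cell
areas follow the exact spherical formula A = R^2 * dlon * (sin(lat_n) -
sin(lat_s)), so that the areas sum to the surface area of the sphere and are
proportional to cos(latitude) at fine resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_M = 6.371e6
EARTH_SURFACE_AREA_M2 = 4.0 * np.pi * EARTH_RADIUS_M**2


@dataclass(frozen=True)
class GridSpec:
    """A regular global lat/lon grid.

    Attributes
    ----------
    n_lon, n_lat
        Number of cells along longitude / latitude.
    lat_centers, lon_centers
        Cell-center coordinates in degrees; latitudes in (-90, 90),
        longitudes in [-180, 180).
    cell_area
        Cell areas in m^2, shape ``(n_lat, n_lon)``.
    """

    n_lon: int
    n_lat: int
    lat_centers: np.ndarray = field(repr=False)
    lon_centers: np.ndarray = field(repr=False)
    cell_area: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lat_field(self) -> np.ndarray:
        """Latitude of every cell, shape ``(n_lat, n_lon)``."""
        return np.broadcast_to(self.lat_centers[:, None], self.shape)


def make_grid(n_lon: int, n_lat: int) -> GridSpec:
    """Build a regular global grid with exact spherical cell areas.

    Parameters
    ----------
    n_lon, n_lat
        Grid dimensions; both must be >= 4.
    """
    if n_lon < 4 or n_lat < 4:
        raise ValueError(f"grid dimensions must be >= 4, got ({n_lon}, {n_lat})")
    lat_edges = np.linspace(-90.0, 90.0, n_lat + 1)
    lon_edges = np.linspace(-180.0, 180.0, n_lon + 1)
    lat_centers = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon_centers = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    dlon_rad = np.deg2rad(360.0 / n_lon)
    sin_edges = np.sin(np.deg2rad(lat_edges))
    band_area = EARTH_RADIUS_M**2 * dlon_rad * np.diff(sin_edges)
    cell_area = np.repeat(band_area[:, None], n_lon, axis=1)
    return GridSpec(
        n_lon=n_lon,
        n_lat=n_lat,
        lat_centers=lat_centers,
        lon_centers=lon_centers,
        cell_area=cell_area,
    )


def area_weighted_mean(field2d: np.ndarray, grid: GridSpec, mask: np.ndarray | None = None) -> float:
    """Area-weighted mean of a field, optionally restricted to a mask."""
    w = grid.cell_area if mask is None else grid.cell_area * mask
    tot = float(w.sum())
    if tot == 0.0:
        return 0.0
    return float((field2d * w).sum() / tot)
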