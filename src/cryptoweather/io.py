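"""xarray/netCDF and CSV output helpers (CF-style dimension names)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr

from .climate import CLIMATE_VARS, MonthlyClimate
from .geography import Paleogeography
from .grid import GridSpec
from .vegetation import VegFields
from .weathering import WeatheringResult


def _coords(grid: GridSpec) -> dict:
    return {"lat": grid.lat_centers, "lon": grid.lon_centers}


def paleogeography_to_dataset(paleo: Paleogeography) -> xr.Dataset:
    return xr.Dataset(
        {
            "land_mask": (("lat", "lon"), paleo.land_mask.astype(np.int8)),
            "elevation": (("lat", "lon"), paleo.elevation, {"units": "m"}),
            "glacier_mask": (("lat", "lon"), paleo.glacier_mask.astype(np.int8)),
            "cell_area": (("lat", "lon"), paleo.grid.cell_area, {"units": "m2"}),
        },
        coords=_coords(paleo.grid),
        attrs={"scenario": paleo.scenario_tag},
    )


def climate_to_dataset(climate: MonthlyClimate) -> xr.Dataset:
    data = {
        name: (("time", "lat", "lon"), getattr(climate, name))
        for name in CLIMATE_VARS
    }
    ds = xr.Dataset(data, coords=_coords(climate.grid) | {"time": np.arange(12)})
    ds.attrs["co2_pal"] = climate.co2_pal
    return ds


def veg_to_dataset(veg: VegFields, weath: WeatheringResult | None = None) -> xr.Dataset:
    data = {
        "potential_npp": (("lat", "lon"), veg.potential_npp, {"units": "g C m-2 yr-1"}),
        "gpp": (("lat", "lon"), veg.gpp, {"units": "g C m-2 yr-1"}),
        "cover": (("lat", "lon"), veg.cover),
        "biomass": (("lat", "lon"), veg.biomass, {"units": "g C m-2"}),
        "runoff": (("lat", "lon"), veg.runoff, {"units": "mm yr-1"}),
        "vegetated_mask": (("lat", "lon"), veg.vegetated_mask.astype(np.int8)),
    }
    if weath is not None:
        data |= {
            "w_npp": (("lat", "lon"), weath.w_npp, {"units": "m yr-1"}),
            "w_erosion": (("lat", "lon"), weath.w_erosion, {"units": "m yr-1"}),
            "w_runoff": (("lat", "lon"), weath.w_runoff, {"units": "m yr-1"}),
            "w_realized": (("lat", "lon"), weath.w_realized, {"units": "m yr-1"}),
            "realized_npp": (("lat", "lon"), weath.realized_npp, {"units": "g C m-2 yr-1"}),
            "limit_code": (
                ("lat", "lon"),
                np.select(
                    [weath.limiting_factor == "npp", weath.limiting_factor == "erosion"],
                    [0, 1], default=2,
                ).astype(np.int8),
                {"flag_meanings": "0=npp 1=erosion 2=runoff"},
            ),
        }
    return xr.Dataset(data, coords=_coords(veg.grid))


def write_netcdf(ds: xr.Dataset, path: str | Path) -> None:
    """Write a dataset as NETCDF3 (scipy engine; no external netCDF library)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine="scipy")


def paleogeography_to_csv(paleo: Paleogeography, directory: str | Path) -> None:
    """Write land mask / elevation / glacier mask as plain CSV matrices."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "land_mask.csv", paleo.land_mask.astype(int), fmt="%d", delimiter=",")
    np.savetxt(d / "elevation.csv", paleo.elevation, fmt="%.2f", delimiter=",")
    np.savetxt(d / "glacier_mask.csv", paleo.glacier_mask.astype(int), fmt="%d", delimiter=",")
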