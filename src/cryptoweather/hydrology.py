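"""Poikilohydric water reservoir and snowpack dynamics.

The thallus is a passive bucket: water arrives as rain, dew (at night under
near-saturated air) and snowmelt; it leaves by evaporation, bounded both by
the stored amount and by an equilibrium-evaporation energy bound; anything
above the storage capacity theta_max runs off immediately.  The update is
constructed so the closure input - evaporation - runoff = delta storage
holds to machine precision.

Snow is a single degree-day pack per cell with a lateral (glacier-flow)
loss term; persistent net accumulation marks the cell glaciated, which
excludes vegetation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .species import SpeciesParams

SIGMA_SB = 5.670374419e-8
LATENT_HEAT_VAP = 2.45e6   # J kg-1
PSYCHROMETRIC = 66.0       # Pa K-1

DEW_RH_THRESHOLD = 0.95
DEW_RATE_MM_H = 0.03       # max dewfall per hour at saturation

SNOW_DDF_MM_H_K = 0.2      # degree-hour melt factor, mm h-1 K-1
SNOW_LATERAL_PER_H = 2e-6  # fractional lateral (glacier flow) loss per hour
SNOW_COVER_SWE = 10.0      # kg m-2 above which vegetation sits under snow


@dataclass
class SpeciesState:
    water_content: float = 0.0   # kg m-2, in [0, theta_max]
    biomass: float = 0.0         # kg C m-2
    alive: bool = True
    accumulated_npp: float = 0.0 # kg C m-2


@dataclass
class SnowState:
    swe: float = 0.0             # kg m-2 snow-water equivalent
    glaciated: bool = False


@njit(cache=True)
def _sat_slope_pa_k(t_c: float) -> float:
    es = 611.2 * np.exp(17.62 * t_c / (t_c + 243.12))
    return es * 17.62 * 243.12 / (t_c + 243.12) ** 2


@njit(cache=True)
def _equilibrium_evap_mm_h(sw: float, lw: float, temp_c: float, albedo: float) -> float:
    """Energy-bound evaporation rate from equilibrium evaporation (mm h-1)."""
    t_k = temp_c + 273.15
    rnet = sw * (1.0 - albedo) + lw - 0.97 * SIGMA_SB * t_k**4
    if rnet <= 0.0:
        return 0.0
    s = _sat_slope_pa_k(temp_c)
    return s / (s + PSYCHROMETRIC) * rnet / LATENT_HEAT_VAP * 3600.0


@njit(cache=True)
def _water_update(
    storage: float,
    theta_max: float,
    rain_mm: float,
    melt_mm: float,
    sw: float,
    lw: float,
    temp_c: float,
    rh: float,
    albedo: float,
):
    """One-hour bucket update; returns (storage, runoff, dew, evap)."""
    dew = 0.0
    if sw <= 1.0 and rh >= DEW_RH_THRESHOLD and temp_c > 0.0:
        dew = DEW_RATE_MM_H * (rh - DEW_RH_THRESHOLD) / (1.0 - DEW_RH_THRESHOLD)
    storage = storage + rain_mm + melt_mm + dew
    sat = storage / theta_max if theta_max > 0 else 0.0
    e_bound = _equilibrium_evap_mm_h(sw, lw, temp_c, albedo)
    evap = min(storage, e_bound * min(sat, 1.0))
    storage -= evap
    runoff = storage - theta_max if storage > theta_max else 0.0
    storage -= runoff
    return storage, runoff, dew, evap


@njit(cache=True)
def _snow_update(swe: float, snowfall_mm: float, temp_c: float):
    """One-hour snowpack update; returns (swe, melt_mm)."""
    swe += snowfall_mm
    melt = 0.0
    if temp_c > 0.0 and swe > 0.0:
        melt = min(swe, SNOW_DDF_MM_H_K * temp_c)
        swe -= melt
    swe -= SNOW_LATERAL_PER_H * swe  # lateral glacier flow out of the cell
    return swe, melt


# ---------------------------------------------------------------------------
# Public single-step API
# ---------------------------------------------------------------------------

def step_water(
    state: SpeciesState,
    hour: dict[str, float],
    params: SpeciesParams,
    melt_mm: float = 0.0,
) -> tuple[SpeciesState, float, float, float]:
    """Advance the thallus water reservoir by one hour.

    ``hour`` supplies ``shortwave_down``, ``longwave_down``,
    ``air_temperature``, ``relative_humidity`` and ``rainfall`` (mm) for
    the hour.  Returns (state, runoff_mm, dew_mm, evap_mm) with exact
    closure: rain + melt + dew - evap - runoff == delta storage.
    """
    storage, runoff, dew, evap = _water_update(
        state.water_content,
        params.theta_max,
        float(hour["rainfall"]),
        melt_mm,
        float(hour["shortwave_down"]),
        float(hour["longwave_down"]),
        float(hour["air_temperature"]),
        float(hour["relative_humidity"]),
        params.albedo,
    )
    state.water_content = storage
    return state, runoff, dew, evap


@dataclass
class SnowConfig:
    glacier_swe_threshold: float = 2000.0  # kg m-2 marking a glaciated cell


def step_snow(snow: SnowState, hour: dict[str, float], melt_cfg: SnowConfig | None = None):
    """Advance the snowpack one hour; returns (snow_state, melt_mm).

    A prescribed ``glaciated`` flag is sticky: dynamics never clear it.
    """
    melt_cfg = melt_cfg or SnowConfig()
    swe, melt = _snow_update(
        snow.swe, float(hour["snowfall"]), float(hour["air_temperature"])
    )
    snow.swe = swe
    if swe > melt_cfg.glacier_swe_threshold:
        snow.glaciated = True
    return snow, melt
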