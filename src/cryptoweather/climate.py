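"""Synthetic monthly climate fields with GCM-like zonal structure.

The generator imposes, analytically plus smooth noise, the large-scale
statistical structure a paleoclimate GCM would deliver: temperature
decreasing poleward with a seasonal cycle in hemispheric phase opposition, a
wet equator and arid subtropical belts near +-30 deg, monthly-mean
insolation from spherical geometry, and a logarithmic land-temperature
response to CO2 (default 3 degC per doubling) with an optional extra
cooling term at low CO2 where the log law breaks down.

The calendar is a 360-day model year: 12 months of 30 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geography import Paleogeography
from .grid import GridSpec

N_MONTHS = 12
DAYS_PER_MONTH = 30
HOURS_PER_YEAR = N_MONTHS * DAYS_PER_MONTH * 24  # 8640

SIGMA_SB = 5.670374419e-8  # W m-2 K-4
SOLAR_CONSTANT = 1361.0    # W m-2

#: The seven climate drivers of the vegetation model.
CLIMATE_VARS = (
    "shortwave_down",    # W m-2
    "longwave_down",     # W m-2
    "rainfall",          # mm month-1
    "snowfall",          # mm month-1
    "air_temperature",   # degC
    "wind_speed",        # m s-1
    "relative_humidity", # fraction
)


@dataclass
class ClimateConfig:
    """Tunables of the synthetic climate; defaults emulate a hot, high-CO2
    Ordovician reference state at ``co2_ref_pal``."""

    co2_ref_pal: float = 8.0
    #: degC of land warming per CO2 doubling.
    temp_sensitivity_per_doubling: float = 3.0
    #: Extra cooling coefficient applied below co2_ref (degC per (log2 deficit)^2);
    #: mimics the breakdown of the log CO2-temperature law at low CO2.
    low_co2_cooling: float = 0.5
    equator_temp_c: float = 30.0        # annual-mean sea-level equator temperature at co2_ref
    pole_equator_contrast_c: float = 36.0
    seasonal_amp_pole_c: float = 14.0   # seasonal half-amplitude at the poles (land)
    ocean_seasonality: float = 0.4      # seasonal damping over ocean
    lapse_rate_c_per_km: float = 6.5
    rain_equator_mm_month: float = 210.0
    rain_midlat_mm_month: float = 85.0
    rain_base_mm_month: float = 12.0
    itcz_shift_deg: float = 8.0
    noise_temp_c: float = 0.4
    noise_rain_frac: float = 0.15
    #: Fractional rainfall increase per degC of CO2-driven warming
    #: (Clausius-Clapeyron-like scaling of the hydrological cycle).
    rain_per_warming_frac: float = 0.04
    wind_mean_ms: float = 5.0
    atm_transmissivity: float = 0.55


@dataclass
class MonthlyClimate:
    """Monthly climatology: each variable is an array ``(12, n_lat, n_lon)``."""

    grid: GridSpec
    co2_pal: float
    shortwave_down: np.ndarray = field(repr=False)
    longwave_down: np.ndarray = field(repr=False)
    rainfall: np.ndarray = field(repr=False)
    snowfall: np.ndarray = field(repr=False)
    air_temperature: np.ndarray = field(repr=False)
    wind_speed: np.ndarray = field(repr=False)
    relative_humidity: np.ndarray = field(repr=False)

    def variables(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in CLIMATE_VARS}

    def cell(self, i_lat: int, i_lon: int) -> dict[str, np.ndarray]:
        """The 12-month series of every variable at one grid cell."""
        return {k: getattr(self, k)[:, i_lat, i_lon].copy() for k in CLIMATE_VARS}


def solar_declination_deg(month: int) -> float:
    """Monthly-mean solar declination; month 0 is mid northern winter."""
    return -23.44 * np.cos(2.0 * np.pi * (month + 0.5) / N_MONTHS)


def daily_mean_insolation(lat_deg: np.ndarray, month: int) -> np.ndarray:
    """Top-of-atmosphere daily-mean insolation (W m-2) from spherical geometry."""
    phi = np.deg2rad(lat_deg)
    delta = np.deg2rad(solar_declination_deg(month))
    cos_h0 = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    h0 = np.arccos(cos_h0)  # half day length in radians
    q = (SOLAR_CONSTANT / np.pi) * (
        h0 * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(h0)
    )
    return np.maximum(q, 0.0)


def co2_temperature_shift(co2_pal: float, cfg: ClimateConfig) -> float:
    """Land temperature shift (degC) relative to the reference CO2 level."""
    shift = cfg.temp_sensitivity_per_doubling * np.log2(co2_pal / cfg.co2_ref_pal)
    if co2_pal < cfg.co2_ref_pal:
        shift -= cfg.low_co2_cooling * np.log2(cfg.co2_ref_pal / co2_pal) ** 2
    return float(shift)


def _sat_vapor_pressure_pa(t_c: np.ndarray) -> np.ndarray:
    return 611.2 * np.exp(17.62 * t_c / (t_c + 243.12))


def generate_monthly_climate(
    paleo: Paleogeography,
    co2_pal: float,
    seed: int,
    cfg: ClimateConfig | None = None,
) -> MonthlyClimate:
    """Generate a deterministic 12-month synthetic climatology.

    Zonal-mean temperature decreases poleward; annual rainfall peaks at the
    equator with subtropical minima near +-30 deg; the seasonal cycle is in
    phase opposition between hemispheres; land temperature carries the CO2
    shift of :func:`co2_temperature_shift`.
    """
    if co2_pal <= 0:
        raise ValueError(f"co2_pal must be positive, got {co2_pal}")
    cfg = cfg or ClimateConfig()
    grid = paleo.grid
    lat = grid.lat_field
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(23,)))
    shape = (N_MONTHS, grid.n_lat, grid.n_lon)

    land = paleo.land_mask
    dT_co2 = co2_temperature_shift(co2_pal, cfg)
    sin2 = np.sin(np.deg2rad(lat)) ** 2

    temp = np.empty(shape)
    sw = np.empty(shape)
    rain_total = np.empty(shape)
    rh = np.empty(shape)
    wind = np.empty(shape)

    # Smooth spatial noise shared across months (stationary pattern) plus a
    # small per-month component keeps fields GCM-plausibly wiggly.
    from .geography import _smooth_noise

    pat_t = _smooth_noise(rng, grid.shape, sigma=max(1.0, grid.n_lat / 12))
    pat_r = _smooth_noise(rng, grid.shape, sigma=max(1.0, grid.n_lat / 12))

    season_sign = np.sin(np.deg2rad(lat))  # hemispheric phase opposition
    for m in range(N_MONTHS):
        season = np.cos(2.0 * np.pi * (m + 0.5 - 6.5) / N_MONTHS)  # +1 in NH summer (month 6)
        amp = cfg.seasonal_amp_pole_c * np.abs(season_sign) ** 1.5
        amp = np.where(land, amp, amp * cfg.ocean_seasonality)
        t = (
            cfg.equator_temp_c
            - cfg.pole_equator_contrast_c * sin2
            + amp * season * np.sign(season_sign)
            - cfg.lapse_rate_c_per_km * paleo.elevation / 1000.0
            + cfg.noise_temp_c * pat_t
        )
        t = np.where(land, t + dT_co2, t + 0.6 * dT_co2)
        temp[m] = t

        # Rainfall: equatorial peak following a migrating ITCZ, mid-latitude
        # storm-track peak, subtropical minima near +-30.
        itcz = cfg.itcz_shift_deg * season
        rain = (
            cfg.rain_equator_mm_month * np.exp(-(((lat - itcz) / 14.0) ** 2))
            + cfg.rain_midlat_mm_month * np.exp(-(((np.abs(lat) - 52.0) / 16.0) ** 2))
            + cfg.rain_base_mm_month
        )
        rain = rain * (1.0 + cfg.noise_rain_frac * pat_r)
        rain = rain * max(0.1, 1.0 + cfg.rain_per_warming_frac * dT_co2)
        rain_total[m] = np.maximum(rain, 0.0)

        toa = daily_mean_insolation(grid.lat_centers, m)[:, None]
        cloud = np.clip(rain_total[m] / 300.0, 0.0, 0.5)
        sw[m] = np.maximum(toa * cfg.atm_transmissivity * (1.0 - 0.5 * cloud), 0.0)

        rh_zonal = (
            0.74
            - 0.30 * np.exp(-(((np.abs(lat) - 28.0) / 12.0) ** 2))
            + 0.12 * np.exp(-(((lat - itcz) / 12.0) ** 2))
            + 0.08 * np.abs(season_sign)
        )
        rh[m] = np.clip(rh_zonal + 0.03 * pat_r, 0.02, 0.98)

        wind[m] = np.clip(
            cfg.wind_mean_ms + 2.5 * np.sin(np.deg2rad(2.0 * np.abs(lat))) + 0.3 * pat_t,
            0.5,
            None,
        )

    # Rain/snow partition by a smooth temperature sigmoid around 0 degC.
    snow_frac = 1.0 / (1.0 + np.exp(temp / 1.5))
    snowfall = rain_total * snow_frac
    rainfall = rain_total - snowfall

    # Downwelling longwave from air temperature and humidity.
    t_k = temp + 273.15
    emiss = np.clip(0.62 + 0.18 * rh + 0.015 * np.log2(max(co2_pal, 1e-6)), 0.0, 1.0)
    lw = emiss * SIGMA_SB * t_k**4

    return MonthlyClimate(
        grid=grid,
        co2_pal=float(co2_pal),
        shortwave_down=sw,
        longwave_down=lw,
        rainfall=rainfall,
        snowfall=snowfall,
        air_temperature=temp,
        wind_speed=wind,
        relative_humidity=rh,
    )
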