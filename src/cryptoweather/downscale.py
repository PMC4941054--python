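"""Stochastic weather generator: monthly climatology to hourly forcing.

State variables (temperature, humidity, wind, longwave) get deterministic
diurnal cycles whose monthly means equal the monthly input exactly; flux
variables (shortwave, rain, snow) are distributed over the month — shortwave
as a daylight half-sine from latitude and season, precipitation as random
wet events with exponential dry/wet spell lengths — and then rescaled so the
monthly total matches exactly.  Conservation to 1e-6 relative is the
generator's contract; the event statistics themselves are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate import DAYS_PER_MONTH, HOURS_PER_YEAR, N_MONTHS, solar_declination_deg

HOURS_PER_MONTH = DAYS_PER_MONTH * 24


@dataclass
class WeatherGenConfig:
    diurnal_temp_amplitude_c: float = 6.0   # half-amplitude of the diurnal cycle
    diurnal_rh_amplitude: float = 0.12      # capped so humidity never clips
    temp_peak_hour: float = 14.0
    wet_hour_mean: float = 4.0              # mean wet-spell length, hours
    wet_fraction_base: float = 0.03         # wet-hour fraction at zero rain
    wet_fraction_per_mm: float = 1.0 / 900.0
    wet_fraction_max: float = 0.35


@dataclass
class HourlyForcing:
    """One 360-day year of hourly drivers for a single grid cell.

    Arrays have length ``HOURS_PER_YEAR`` (8640).  Shortwave/longwave are
    W m-2, precipitation mm h-1, temperature degC, wind m s-1, humidity a
    fraction.
    """

    lat_deg: float
    shortwave_down: np.ndarray = field(repr=False)
    longwave_down: np.ndarray = field(repr=False)
    rainfall: np.ndarray = field(repr=False)
    snowfall: np.ndarray = field(repr=False)
    air_temperature: np.ndarray = field(repr=False)
    wind_speed: np.ndarray = field(repr=False)
    relative_humidity: np.ndarray = field(repr=False)

    @property
    def n_hours(self) -> int:
        return self.shortwave_down.size


def day_length_hours(lat_deg: float, month: int) -> float:
    """Astronomical day length for the given month's mean declination."""
    phi = np.deg2rad(lat_deg)
    delta = np.deg2rad(solar_declination_deg(month))
    cos_h0 = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    return float(24.0 * np.arccos(cos_h0) / np.pi)


def _diurnal_cosine(peak_hour: float) -> np.ndarray:
    """Zero-mean unit cosine over 24 hourly samples peaking at ``peak_hour``."""
    h = np.arange(24)
    return np.cos(2.0 * np.pi * (h - peak_hour) / 24.0)


def _shortwave_weights(lat_deg: float, month: int) -> np.ndarray:
    """Relative half-sine daylight weights for one 24-h day (may be all 0)."""
    n = day_length_hours(lat_deg, month)
    h = np.arange(24) + 0.5
    if n <= 0.0:
        return np.zeros(24)
    sunrise = 12.0 - n / 2.0
    x = (h - sunrise) / n
    w = np.where((x > 0.0) & (x < 1.0), np.sin(np.pi * np.clip(x, 0.0, 1.0)), 0.0)
    return w


def _precip_events(total_mm: float, rng: np.random.Generator, cfg: WeatherGenConfig) -> np.ndarray:
    """Hourly precipitation (mm/h) for one month summing exactly to total_mm."""
    if total_mm < 0:
        raise ValueError(f"negative monthly precipitation: {total_mm}")
    out = np.zeros(HOURS_PER_MONTH)
    if total_mm == 0.0:
        return out
    f_wet = min(cfg.wet_fraction_max, cfg.wet_fraction_base + cfg.wet_fraction_per_mm * total_mm)
    dry_mean = cfg.wet_hour_mean * (1.0 - f_wet) / f_wet
    wet = np.zeros(HOURS_PER_MONTH, dtype=bool)
    t = 0.0
    # Alternating exponential dry/wet spells.
    while t < HOURS_PER_MONTH:
        t += rng.exponential(dry_mean)
        dur = max(1.0, rng.exponential(cfg.wet_hour_mean))
        a, b = int(t), min(int(np.ceil(t + dur)), HOURS_PER_MONTH)
        if a < HOURS_PER_MONTH:
            wet[a:b] = True
        t += dur
    if not wet.any():
        wet[rng.integers(0, HOURS_PER_MONTH)] = True
    intensity = rng.exponential(1.0, size=int(wet.sum())) + 0.05
    out[wet] = intensity
    out *= total_mm / out.sum()  # exact monthly conservation
    return out


def downscale_to_hourly(
    monthly_cell: dict[str, np.ndarray],
    lat_deg: float,
    seed: int,
    cfg: WeatherGenConfig | None = None,
) -> HourlyForcing:
    """Downscale one cell's 12-month climatology to an hourly model year.

    ``monthly_cell`` maps each climate variable name to its 12 monthly
    values (as returned by :meth:`MonthlyClimate.cell`).  Every variable
    conserves its monthly mean (states) or total (fluxes) exactly.
    """
    cfg = cfg or WeatherGenConfig()
    for name in ("rainfall", "snowfall"):
        if np.any(np.asarray(monthly_cell[name]) < 0):
            raise ValueError(f"negative monthly {name}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(37,)))

    temp = np.empty(HOURS_PER_YEAR)
    sw = np.empty(HOURS_PER_YEAR)
    lw = np.empty(HOURS_PER_YEAR)
    rain = np.empty(HOURS_PER_YEAR)
    snow = np.empty(HOURS_PER_YEAR)
    wind = np.empty(HOURS_PER_YEAR)
    rh = np.empty(HOURS_PER_YEAR)

    cos_t = _diurnal_cosine(cfg.temp_peak_hour)
    cos_rh = _diurnal_cosine(cfg.temp_peak_hour - 12.0)  # anti-phase to temperature

    for m in range(N_MONTHS):
        sl = slice(m * HOURS_PER_MONTH, (m + 1) * HOURS_PER_MONTH)
        t_m = float(monthly_cell["air_temperature"][m])
        temp[sl] = t_m + cfg.diurnal_temp_amplitude_c * np.tile(cos_t, DAYS_PER_MONTH)

        rh_m = float(monthly_cell["relative_humidity"][m])
        amp = min(cfg.diurnal_rh_amplitude, rh_m, 1.0 - rh_m)
        rh[sl] = rh_m + amp * np.tile(cos_rh, DAYS_PER_MONTH)

        lw[sl] = float(monthly_cell["longwave_down"][m])
        wind[sl] = float(monthly_cell["wind_speed"][m])

        s_m = float(monthly_cell["shortwave_down"][m])
        w = _shortwave_weights(lat_deg, m)
        if w.sum() == 0.0:
            sw[sl] = s_m  # polar night with nonzero monthly flux: uniform
        else:
            day = w * (24.0 * s_m / w.sum())
            sw[sl] = np.tile(day, DAYS_PER_MONTH)

        rain[sl] = _precip_events(float(monthly_cell["rainfall"][m]), rng, cfg)
        snow[sl] = _precip_events(float(monthly_cell["snowfall"][m]), rng, cfg)

    return HourlyForcing(
        lat_deg=lat_deg,
        shortwave_down=sw,
        longwave_down=lw,
        rainfall=rain,
        snowfall=snow,
        air_temperature=temp,
        wind_speed=wind,
        relative_humidity=rh,
    )
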