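"""Reference weathering computations: Budyko runoff, GEM-CO2, GEOCARB.

These provide the abiotic / present-day context against which the
vegetation-driven estimate is judged:

* Budyko runoff — partitions annual precipitation into evaporation and
  runoff via the aridity index, with potential evaporation from the
  equilibrium-evaporation energy bound.
* GEM-CO2 — empirical weathering flux linear in runoff per lithology
  class; slopes are normalized so a reference (present-day-like) runoff
  climatology reproduces configured silicate and carbonate calcium fluxes.
* GEOCARB-style scaling — scales today's silicate and carbonate calcium
  fluxes to another climate via standard temperature/runoff response
  factors, an uplift factor, a land-area factor and the pre-vascular
  biotic factor (0.25), then converts to rock volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .weathering import ca_flux_to_rock_volume

SILICATE_CLASSES = ("sandstone", "shale", "granite", "rhyolite", "basalt")
CARBONATE_CLASSES = ("limestone",)

SECONDS_PER_YEAR = 360 * 24 * 3600.0  # 360-day model year
LATENT_HEAT_VAP = 2.45e6
PSYCHROMETRIC = 66.0


# ---------------------------------------------------------------------------
# Budyko runoff
# ---------------------------------------------------------------------------

def _sat_slope_pa_k(t_c):
    es = 611.2 * np.exp(17.62 * t_c / (t_c + 243.12))
    return es * 17.62 * 243.12 / (t_c + 243.12) ** 2


def equilibrium_pet_mm_yr(net_radiation_w_m2, temp_c):
    """Potential evaporation (mm yr-1) from the equilibrium-evaporation bound."""
    rnet = np.maximum(np.asarray(net_radiation_w_m2, dtype=float), 0.0)
    s = _sat_slope_pa_k(np.asarray(temp_c, dtype=float))
    kg_m2_s = s / (s + PSYCHROMETRIC) * rnet / LATENT_HEAT_VAP
    return kg_m2_s * SECONDS_PER_YEAR


def budyko_runoff(precip_mm_yr, net_radiation_w_m2, temp_c):
    """Annual runoff (mm yr-1) from the Budyko curve.

    E/P = sqrt(phi * tanh(1/phi) * (1 - exp(-phi))) with aridity index
    phi = PET/P; runoff = P - E, guaranteed within [max(0, P-PET), P].
    """
    p = np.asarray(precip_mm_yr, dtype=float)
    if np.any(p < 0):
        raise ValueError("precipitation must be nonnegative")
    pet = equilibrium_pet_mm_yr(net_radiation_w_m2, temp_c)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        phi = np.where(p > 0, pet / np.maximum(p, 1e-300), np.inf)
        ep = np.sqrt(phi * np.tanh(1.0 / phi) * (1.0 - np.exp(-phi)))
    ep = np.where(p > 0, np.nan_to_num(ep, nan=0.0), 0.0)
    evap = np.clip(ep, 0.0, 1.0) * p
    runoff = np.clip(p - evap, 0.0, p)
    return runoff if runoff.ndim else float(runoff)


# ---------------------------------------------------------------------------
# GEM-CO2
# ---------------------------------------------------------------------------

@dataclass
class GemCo2Table:
    """Per-lithology weathering slopes, mol Ca per m3 of runoff."""

    slopes: dict[str, float] = field(default_factory=lambda: {
        # Relative literature-shaped slopes; carbonate outcrops weather
        # roughly an order of magnitude faster than silicates per unit runoff.
        "limestone": 10.0, "basalt": 1.5, "shale": 1.0,
        "granite": 0.8, "rhyolite": 0.7, "sandstone": 0.5,
    })

    def __post_init__(self):
        if any(v < 0 for v in self.slopes.values()):
            raise ValueError("slopes must be nonnegative")


def gem_co2_flux(
    runoff_mm_yr: np.ndarray,
    cell_area_m2: np.ndarray,
    table: GemCo2Table,
    fractions: dict[str, float],
    mask: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Global (total, silicate, carbonate) calcium fluxes, mol yr-1.

    Per-cell flux = runoff * sum_i fraction_i * slope_i * area; the total is
    exactly the silicate plus the carbonate part.
    """
    if abs(sum(fractions.values()) - 1.0) > 1e-6:
        raise ValueError("lithology fractions must sum to 1")
    runoff_m = np.nan_to_num(np.asarray(runoff_mm_yr, dtype=float)) * 1e-3
    if mask is not None:
        runoff_m = np.where(mask, runoff_m, 0.0)
    base = float((runoff_m * cell_area_m2).sum())  # m3 water yr-1
    sil = base * sum(fractions[c] * table.slopes[c] for c in SILICATE_CLASSES)
    carb = base * sum(fractions[c] * table.slopes[c] for c in CARBONATE_CLASSES)
    return sil + carb, sil, carb


def calibrate_gem_table(
    runoff_mm_yr: np.ndarray,
    cell_area_m2: np.ndarray,
    fractions: dict[str, float],
    silicate_flux_mol_yr: float = 3.4e12,
    carbonate_flux_mol_yr: float = 2.1e12,
    mask: np.ndarray | None = None,
    table: GemCo2Table | None = None,
) -> GemCo2Table:
    """Rescale slopes so the reference runoff field reproduces the
    configured present-day silicate and carbonate calcium fluxes."""
    table = table or GemCo2Table()
    _, sil, carb = gem_co2_flux(runoff_mm_yr, cell_area_m2, table, fractions, mask)
    if sil <= 0 or carb <= 0:
        raise ValueError("reference runoff produces zero flux; cannot calibrate")
    slopes = dict(table.slopes)
    for c in SILICATE_CLASSES:
        slopes[c] *= silicate_flux_mol_yr / sil
    for c in CARBONATE_CLASSES:
        slopes[c] *= carbonate_flux_mol_yr / carb
    return GemCo2Table(slopes=slopes)


# ---------------------------------------------------------------------------
# GEOCARB-style abiotic scaling
# ---------------------------------------------------------------------------

@dataclass
class GeocarbConfig:
    """Standard GEOCARB III response constants and reference fluxes."""

    f_biotic_prevascular: float = 0.25
    f_uplift: float = 1.0
    f_land_area: float = 1.0
    act_silicate: float = 0.09       # K-1, temperature (activation) response
    run_silicate: float = 0.038      # K-1, runoff response
    run_exponent: float = 0.65
    act_carbonate: float = 0.087     # K-1, combined carbonate response
    t0_c: float = 15.0               # reference (present-day) land temperature
    present_day_silicate_flux: float = 3.4e12   # mol Ca yr-1
    present_day_carbonate_flux: float = 2.1e12  # mol Ca yr-1

    def __post_init__(self):
        if not 0 < self.f_biotic_prevascular <= 1:
            raise ValueError("f_biotic_prevascular must be in (0, 1]")
        if self.f_uplift <= 0 or self.f_land_area <= 0:
            raise ValueError("scaling factors must be positive")


def geocarb_abiotic(land_temp_c: float, co2_pal: float,
                    cfg: GeocarbConfig | None = None) -> float:
    """Abiotic weathering (km3 rock yr-1) scaled from present-day fluxes.

    The land temperature is supplied externally (here from the synthetic
    climate, so biotic and abiotic estimates share one forcing); CO2 enters
    only through that temperature.  At the reference state all factors are
    1 and the output is f_biotic * the present-day rock volume.
    """
    if co2_pal <= 0:
        raise ValueError("co2_pal must be positive")
    cfg = cfg or GeocarbConfig()
    dt = land_temp_c - cfg.t0_c
    f_sil = np.exp(cfg.act_silicate * dt) * max(0.0, 1.0 + cfg.run_silicate * dt) ** cfg.run_exponent
    f_carb = max(0.0, 1.0 + cfg.act_carbonate * dt)
    flux = (
        cfg.f_biotic_prevascular * cfg.f_uplift * cfg.f_land_area
        * (cfg.present_day_silicate_flux * f_sil + cfg.present_day_carbonate_flux * f_carb)
    )
    return ca_flux_to_rock_volume(flux)
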