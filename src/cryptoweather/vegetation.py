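"""Cell and grid vegetation simulation with survival filtering.

Each cell runs all artificial species through the hourly kernel once (the
forcing year repeats), then iterates an annual demography for ``n_years``:
biomass grows with NPP and decays with turnover, disturbance resets cover
and biomass every tau_d years, and species whose biomass falls below a
fraction of the seed biomass at an annual checkpoint die out.  Cell-level
NPP, GPP, cover, biomass and runoff are means over the survivors weighted
by NPP accumulated over the simulation; cells where nothing survives are
barren, and glaciated cells (prescribed or from persistent snow
accumulation) exclude vegetation entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate import MonthlyClimate
from .downscale import WeatherGenConfig, downscale_to_hourly, HourlyForcing
from .geography import Paleogeography
from .grid import GridSpec
from .kernel import simulate_forcing_year
from .species import (
    DEFAULT_ETA_CCM,
    DEFAULT_PHI_RR,
    SpeciesParams,
    sample_species,
    scaled_dco2_ranges,
    species_arrays,
)

PPM_PER_PAL = 280.0
KG_C_PER_MOL = 12.011e-3
#: mol photons of PAR per J of shortwave (0.5 PAR fraction x 4.6 umol/J).
PAR_PER_SW = 0.5 * 4.6e-6


@dataclass
class VegConfig:
    """Run configuration of the vegetation simulator."""

    n_species: int = 30
    n_years: int = 50
    tau_d_years: int = 100        # disturbance interval
    co2_pal: float = 8.0          # 8 PAL = 2240 ppm
    o2_fraction: float = 0.14
    eta_ccm: float = DEFAULT_ETA_CCM
    phi_rr: float = DEFAULT_PHI_RR
    dco2_scale_high: float = 1.0  # sensitivity scaling of the d_co2_sat range
    dco2_scale_low: float = 1.0
    activity_threshold: float = 0.10  # saturation below which metabolism stops
    init_saturation: float = 0.5
    turnover_per_year: float = 0.05   # fractional biomass loss per year
    seed_biomass_kg_m2: float = 0.005
    survival_fraction: float = 0.01   # die below this fraction of seed biomass
    cover_half_sat_kg_m2: float = 0.2
    glacier_swe_net_gain: float = 50.0   # kg m-2 yr-1 net gain marking glaciation
    weather: WeatherGenConfig = field(default_factory=WeatherGenConfig)

    @property
    def ambient_co2(self) -> float:
        return self.co2_pal * PPM_PER_PAL * 1e-6


@dataclass
class CellVegResult:
    potential_npp: float      # g C m-2 yr-1
    gpp: float                # g C m-2 yr-1
    cover: float              # fraction
    biomass: float            # g C m-2
    runoff: float             # mm yr-1
    n_survivors: int
    species_weights: np.ndarray
    barren: bool
    glaciated: bool


@dataclass
class VegFields:
    """Gridded vegetation output; NaN outside the valid (land) domain."""

    grid: GridSpec
    potential_npp: np.ndarray = field(repr=False)  # g C m-2 yr-1
    gpp: np.ndarray = field(repr=False)
    cover: np.ndarray = field(repr=False)
    biomass: np.ndarray = field(repr=False)        # g C m-2
    runoff: np.ndarray = field(repr=False)         # mm yr-1
    n_survivors: np.ndarray = field(repr=False)
    vegetated_mask: np.ndarray = field(repr=False) # land, unglaciated, not barren
    glaciated_mask: np.ndarray = field(repr=False)


def _forcing_arrays(forcing: HourlyForcing) -> tuple[np.ndarray, ...]:
    return (
        forcing.shortwave_down,
        forcing.longwave_down,
        forcing.rainfall,
        forcing.snowfall,
        forcing.air_temperature,
        forcing.relative_humidity,
    )


def run_cell(
    species: list[SpeciesParams],
    forcing: HourlyForcing,
    cfg: VegConfig | None = None,
    prescribed_glacier: bool = False,
) -> CellVegResult:
    """Simulate one cell: hourly physiology for the forcing year, then
    annual demography with disturbance and survival filtering."""
    cfg = cfg or VegConfig()
    if len(species) < 1:
        raise ValueError("need at least one species")
    if forcing.n_hours == 0:
        raise ValueError("zero-length forcing")

    if prescribed_glacier:
        return CellVegResult(0.0, 0.0, 0.0, 0.0, 0.0, 0,
                             np.zeros(len(species)), True, True)

    arr = species_arrays(species)
    sw, lw, rain, snowfall, temp, rh = _forcing_arrays(forcing)
    gpp_mol, resp_mol, npp_mol, runoff_mm, _active, swe_end, _swe_max, _snowcov = (
        simulate_forcing_year(
            sw, lw, rain, snowfall, temp, rh,
            arr["vcmax_ref"], arr["jmax_ref"], arr["q10"], arr["resp_ref"],
            arr["d_co2_sat"], arr["theta_max"], arr["albedo"], arr["t_opt"],
            species[0].eta_ccm, cfg.ambient_co2, cfg.o2_fraction,
            cfg.activity_threshold, PAR_PER_SW, cfg.init_saturation,
        )
    )

    # Persistent net snow accumulation over the repeated year -> glaciated.
    if swe_end > cfg.glacier_swe_net_gain:
        return CellVegResult(0.0, 0.0, 0.0, 0.0, 0.0, 0,
                             np.zeros(len(species)), True, True)

    npp_kg = npp_mol * KG_C_PER_MOL  # annual per-area NPP, kg C m-2 yr-1
    gpp_kg = gpp_mol * KG_C_PER_MOL

    n_sp = len(species)
    biomass = np.full(n_sp, cfg.seed_biomass_kg_m2)
    alive = np.ones(n_sp, dtype=bool)
    acc_npp = np.zeros(n_sp)
    floor = cfg.survival_fraction * cfg.seed_biomass_kg_m2

    # Annual demography: the species share one canopy, so each species'
    # ground cover saturates collectively (cover_i = b_i / (sum b + h)) and
    # its per-ground-area carbon gain is its per-thallus-area rate times its
    # cover.  Growth from seed is exponential and dominant species suppress
    # marginal ones (competitive exclusion), so the NPP-accumulation weights
    # concentrate on the most productive trait combinations.
    for year in range(1, cfg.n_years + 1):
        stand = biomass.sum()
        cover_now = biomass / (stand + cfg.cover_half_sat_kg_m2)
        gain = npp_kg * cover_now
        biomass[alive] += gain[alive] - cfg.turnover_per_year * biomass[alive]
        np.clip(biomass, 0.0, None, out=biomass)
        acc_npp[alive] += np.maximum(gain[alive], 0.0)
        alive &= biomass > floor
        if year % cfg.tau_d_years == 0 and year < cfg.n_years:
            biomass[alive] = cfg.seed_biomass_kg_m2  # disturbance reset

    survivors = alive & (acc_npp > 0.0)
    if not survivors.any():
        return CellVegResult(0.0, 0.0, 0.0, 0.0, 0.0, 0,
                             np.zeros(n_sp), True, False)

    w = np.where(survivors, acc_npp, 0.0)
    w = w / w.sum()
    biomass = np.where(survivors, biomass, 0.0)
    stand = biomass.sum()
    cover_total = stand / (stand + cfg.cover_half_sat_kg_m2)
    return CellVegResult(
        potential_npp=float((w * npp_kg).sum() * 1000.0),
        gpp=float((w * gpp_kg).sum() * 1000.0),
        cover=float(cover_total),
        biomass=float(stand * 1000.0),
        runoff=float((w * runoff_mm).sum()),
        n_survivors=int(survivors.sum()),
        species_weights=w,
        barren=False,
        glaciated=False,
    )


def run_grid(
    paleo: Paleogeography,
    climate: MonthlyClimate,
    cfg: VegConfig | None = None,
    seed: int = 0,
    species: list[SpeciesParams] | None = None,
) -> VegFields:
    """Run the vegetation simulation over all land, non-glaciated cells.

    One species pool (sampled from ``seed``) is shared by all cells; each
    cell gets an independent weather-generator substream.
    """
    cfg = cfg or VegConfig()
    grid = paleo.grid
    if climate.grid.shape != grid.shape:
        raise ValueError("paleogeography and climate grids do not match")

    if species is None:
        species = sample_species(
            cfg.n_species,
            ranges=scaled_dco2_ranges(cfg.dco2_scale_high, cfg.dco2_scale_low),
            seed=seed,
            phi_rr=cfg.phi_rr,
            eta_ccm=cfg.eta_ccm,
        )

    nan = np.full(grid.shape, np.nan)
    out = VegFields(
        grid=grid,
        potential_npp=nan.copy(), gpp=nan.copy(), cover=nan.copy(),
        biomass=nan.copy(), runoff=nan.copy(),
        n_survivors=np.zeros(grid.shape),
        vegetated_mask=np.zeros(grid.shape, dtype=bool),
        glaciated_mask=paleo.glacier_mask.copy(),
    )

    for i in range(grid.n_lat):
        for j in range(grid.n_lon):
            if not paleo.land_mask[i, j]:
                continue
            flat = i * grid.n_lon + j
            cell_seed = int(
                np.random.SeedSequence(seed, spawn_key=(53, flat))
                .generate_state(1, dtype=np.uint32)[0]
                % (2**31)
            )
            if paleo.glacier_mask[i, j]:
                for f in ("potential_npp", "gpp", "cover", "biomass", "runoff"):
                    getattr(out, f)[i, j] = 0.0
                continue
            forcing = downscale_to_hourly(
                climate.cell(i, j), float(grid.lat_centers[i]), cell_seed, cfg.weather
            )
            res = run_cell(species, forcing, cfg)
            out.potential_npp[i, j] = res.potential_npp
            out.gpp[i, j] = res.gpp
            out.cover[i, j] = res.cover
            out.biomass[i, j] = res.biomass
            out.runoff[i, j] = res.runoff
            out.n_survivors[i, j] = res.n_survivors
            out.vegetated_mask[i, j] = not (res.barren or res.glaciated)
            if res.glaciated:
                out.glaciated_mask[i, j] = True
    return out
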