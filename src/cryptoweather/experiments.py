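"""Named end-to-end experiments: baseline, sweeps and sensitivity scenarios.

Each experiment executes the full pipeline — synthetic paleogeography and
climate, vegetation simulation, limit-based weathering, global totals — at
desk scale and returns tidy tables; with an output directory it also
writes a summary CSV, netCDF fields and a JSON run manifest (config hash +
seed), so any run is reproducible bit-for-bit from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cwio
from .baselines import GeocarbConfig, calibrate_gem_table, budyko_runoff, gem_co2_flux, geocarb_abiotic
from .carbonate import SoilChemistry, calcite_equilibrium_ca
from .climate import ClimateConfig, generate_monthly_climate
from .downscale import downscale_to_hourly
from .geography import generate_paleogeography
from .grid import area_weighted_mean, make_grid
from .species import SpeciesParams, sample_species
from .vegetation import VegConfig, run_cell, run_grid
from .weathering import (
    DEFAULT_K_E,
    RockGeochem,
    Stoichiometry,
    ca_flux_to_rock_volume,
    global_totals,
    weathering_from_vegetation,
)
from .physiology import net_assimilation

EXPERIMENTS = (
    "baseline",
    "co2_sweep",
    "species_sweep",
    "hirnantian",
    "param_sensitivity",
    "today_reference",
    "response_curves",
)

CO2_SWEEP_PAL = (3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 24.0)
SPECIES_SWEEP = (10, 30, 100)

SUMMARY_COLUMNS = ["scenario", "npp", "gpp", "cover", "biomass", "weathering"]


class BarrenRunError(RuntimeError):
    """Raised when a run has no surviving species to select from."""


@dataclass
class PipelineConfig:
    """Desk-scale defaults of the full pipeline."""

    n_lon: int = 32
    n_lat: int = 16
    land_fraction: float = 0.25
    co2_pal: float = 8.0
    scenario: str = "baseline"
    veg: VegConfig = field(default_factory=lambda: VegConfig(n_species=16, n_years=30))
    stoich: Stoichiometry = field(default_factory=Stoichiometry)
    rock: RockGeochem = field(default_factory=RockGeochem)
    soil: SoilChemistry = field(default_factory=SoilChemistry)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    k_e: float = DEFAULT_K_E
    npp_multiplier: float = 1.0  # minimum-CO2-sensitivity scenario knob


@dataclass
class ExperimentConfig:
    name: str = "baseline"
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    output_dir: str | None = None
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self):
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; expected one of {EXPERIMENTS}")


@dataclass
class PipelineResult:
    paleo: object
    climate: object
    veg: object
    weathering: object
    summary: object  # GlobalSummary


def run_pipeline(pcfg: PipelineConfig, seed: int,
                 species: list[SpeciesParams] | None = None) -> PipelineResult:
    """Climate -> vegetation -> weathering -> totals, one scenario."""
    grid = make_grid(pcfg.n_lon, pcfg.n_lat)
    paleo = generate_paleogeography(grid, seed, scenario=pcfg.scenario,
                                    land_fraction=pcfg.land_fraction)
    vcfg = replace(pcfg.veg, co2_pal=pcfg.co2_pal)
    climate = generate_monthly_climate(paleo, pcfg.co2_pal, seed, pcfg.climate)
    veg = run_grid(paleo, climate, vcfg, seed=seed, species=species)
    if pcfg.npp_multiplier != 1.0:
        veg = dataclasses.replace(
            veg, potential_npp=veg.potential_npp * pcfg.npp_multiplier,
            gpp=veg.gpp * pcfg.npp_multiplier,
        )
    weath = weathering_from_vegetation(
        veg, paleo.elevation, pcfg.stoich, pcfg.rock, pcfg.soil, pcfg.k_e
    )
    summary = global_totals(weath, veg, grid)
    return PipelineResult(paleo, climate, veg, weath, summary)


def _row(scenario: str, s) -> dict:
    return {
        "scenario": scenario, "npp": s.npp_gt_yr, "gpp": s.gpp_gt_yr,
        "cover": s.cover, "biomass": s.biomass_gt, "weathering": s.weathering_km3_yr,
    }


def mean_land_temperature(res: PipelineResult) -> float:
    """Area-weighted annual-mean land surface temperature (degC)."""
    ann = res.climate.air_temperature.mean(axis=0)
    return area_weighted_mean(ann, res.paleo.grid, res.paleo.land_mask)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def _experiment_baseline(cfg: ExperimentConfig):
    res = run_pipeline(cfg.pipeline, cfg.seed)
    table = pd.DataFrame([_row("baseline", res.summary)], columns=SUMMARY_COLUMNS)
    fields = {"fields": cwio.veg_to_dataset(res.veg, res.weathering)}
    return table, fields


def _experiment_hirnantian(cfg: ExperimentConfig):
    rows, fields = [], {}
    for tag, scen in (("baseline", "baseline"), ("hirnantian_ice", "hirnantian_ice")):
        res = run_pipeline(replace(cfg.pipeline, scenario=scen), cfg.seed)
        rows.append(_row(tag, res.summary))
        fields[tag] = cwio.veg_to_dataset(res.veg, res.weathering)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS), fields


def _experiment_co2_sweep(cfg: ExperimentConfig):
    levels = cfg.overrides.get("co2_levels", CO2_SWEEP_PAL)
    gc_cfg = cfg.overrides.get("geocarb", None)
    # Reference land temperature at 1 PAL anchors the GEOCARB factors, so the
    # biotic and abiotic estimates share a single CO2->temperature forcing.
    t0 = mean_land_temperature(
        run_pipeline(replace(cfg.pipeline, co2_pal=1.0,
                             veg=replace(cfg.pipeline.veg, n_species=1, n_years=1)),
                     cfg.seed)
    )
    gc_cfg = gc_cfg or GeocarbConfig(t0_c=t0)
    rows = []
    for pal in levels:
        res = run_pipeline(replace(cfg.pipeline, co2_pal=pal), cfg.seed)
        t_land = mean_land_temperature(res)
        rows.append({
            "co2_pal": pal,
            "biotic_km3": res.summary.weathering_km3_yr,
            "abiotic_km3": geocarb_abiotic(t_land, pal, gc_cfg),
            "npp_gt": res.summary.npp_gt_yr,
            "land_temp_c": t_land,
        })
    return pd.DataFrame(rows), {}


def _experiment_species_sweep(cfg: ExperimentConfig):
    counts = cfg.overrides.get("species_counts", SPECIES_SWEEP)
    rows = []
    for n in counts:
        pcfg = replace(cfg.pipeline, veg=replace(cfg.pipeline.veg, n_species=int(n)))
        res = run_pipeline(pcfg, cfg.seed)  # same master seed: paired comparison
        rows.append({"n_species": int(n)} | _row(f"n={n}", res.summary))
    return pd.DataFrame(rows), {}


#: The eight parameter-sensitivity scenarios (plus baseline).
SENSITIVITY_SCENARIOS: dict[str, dict] = {
    "phi_rr_low": {"phi_rr_scale": 0.5},
    "phi_rr_high": {"phi_rr_scale": 2.0},
    "dco2_low": {"dco2_scale_low": 0.5},
    "dco2_high": {"dco2_scale_high": 2.0},
    "eta_ccm_low": {"eta_ccm": 2.0},
    "eta_ccm_high": {"eta_ccm": 45.0},
    "tau_10yr": {"tau_d_years": 10},
    "tau_250yr": {"tau_d_years": 250},
}


def _experiment_param_sensitivity(cfg: ExperimentConfig):
    rows = []

    def veg_with(**kw) -> VegConfig:
        v = cfg.pipeline.veg
        if "phi_rr_scale" in kw:
            v = replace(v, phi_rr=v.phi_rr * kw.pop("phi_rr_scale"))
        return replace(v, **kw)

    res = run_pipeline(cfg.pipeline, cfg.seed)
    rows.append(_row("baseline", res.summary))
    for name, kw in SENSITIVITY_SCENARIOS.items():
        pcfg = replace(cfg.pipeline, veg=veg_with(**dict(kw)))
        rows.append(_row(name, run_pipeline(pcfg, cfg.seed).summary))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS), {}


def _experiment_today_reference(cfg: ExperimentConfig):
    """Present-day-like limit-based and GEM-CO2 weathering estimates."""
    pcfg = replace(cfg.pipeline, co2_pal=1.0)
    grid = make_grid(pcfg.n_lon, pcfg.n_lat)
    paleo = generate_paleogeography(grid, cfg.seed, land_fraction=pcfg.land_fraction)
    climate = generate_monthly_climate(paleo, 1.0, cfg.seed, pcfg.climate)

    ann_t = climate.air_temperature.mean(axis=0)
    precip = (climate.rainfall + climate.snowfall).sum(axis=0)
    sigma = 5.670374419e-8
    rnet = (
        climate.shortwave_down.mean(axis=0) * 0.8
        + climate.longwave_down.mean(axis=0)
        - 0.97 * sigma * (ann_t + 273.15) ** 4
    )
    runoff = budyko_runoff(precip, rnet, ann_t)
    land = paleo.land_mask
    a = grid.cell_area

    ca_eq = calcite_equilibrium_ca(pcfg.soil)
    runoff_flux = float((runoff * 1e-3 * ca_eq * a * land).sum())          # mol yr-1
    ero_flux = float(
        (pcfg.k_e * paleo.elevation * pcfg.rock.ca_molar_conc * a * land).sum()
    )
    limited = float(
        (np.minimum(runoff * 1e-3 * ca_eq, pcfg.k_e * paleo.elevation * pcfg.rock.ca_molar_conc)
         * a * land).sum()
    )
    table = calibrate_gem_table(runoff, a, pcfg.rock.lithology_fractions, mask=land)
    gem_total, gem_sil, gem_carb = gem_co2_flux(
        runoff, a, table, pcfg.rock.lithology_fractions, mask=land
    )
    rows = pd.DataFrame([{
        "runoff_ca_flux_mol": runoff_flux,
        "erosion_ca_flux_mol": ero_flux,
        "limit_based_ca_flux_mol": limited,
        "limit_based_km3": ca_flux_to_rock_volume(limited),
        "gem_total_mol": gem_total,
        "gem_silicate_mol": gem_sil,
        "gem_carbonate_mol": gem_carb,
        "gem_km3": ca_flux_to_rock_volume(gem_total),
    }])
    return rows, {}


# --- response curves -------------------------------------------------------

#: Two laboratory-liverwort-like parameterizations differing mainly in
#: photosynthetic capacity (fixture II has the lower capacity); calibrated
#: so that at 400 ppm CO2, 250 umol m-2 s-1 PAR, 20 degC, saturated water
#: and 21% O2, net assimilation is ~5 and ~2 umol m-2 s-1 respectively.
FIXTURE_SPECIES: dict[str, SpeciesParams] = {
    "fixture_I": SpeciesParams(
        vcmax_ref=2.0e-5, jmax_ref=4.0e-5, q10=2.0, phi_rr=10.0,
        d_co2_sat=1.7e-3, eta_ccm=8.0, theta_max=5.0, albedo=0.2, t_opt=22.0,
    ),
    "fixture_II": SpeciesParams(
        vcmax_ref=8.0e-6, jmax_ref=1.6e-5, q10=2.0, phi_rr=10.0,
        d_co2_sat=3.5e-4, eta_ccm=8.0, theta_max=5.0, albedo=0.2, t_opt=22.0,
    ),
}


def dominant_species(co2_pal: float, seed: int, n_species: int = 30) -> SpeciesParams:
    """The NPP-weight-dominant surviving species of a warm, humid reference
    cell simulated at the given CO2 level."""
    grid = make_grid(8, 8)
    paleo = generate_paleogeography(grid, seed)
    climate = generate_monthly_climate(paleo, co2_pal, seed)
    # A warm, humid near-equator column: use the wettest land cell.
    land = np.argwhere(paleo.land_mask)
    if land.size == 0:
        raise BarrenRunError("no land in reference geography")
    rain = np.nansum(climate.rainfall, axis=0)
    i, j = max(map(tuple, land), key=lambda ij: rain[ij])
    species = sample_species(n_species, seed=seed)
    vcfg = VegConfig(n_species=n_species, co2_pal=co2_pal)
    forcing = downscale_to_hourly(climate.cell(i, j), float(grid.lat_centers[i]), seed)
    res = run_cell(species, forcing, vcfg)
    if res.n_survivors == 0:
        raise BarrenRunError(f"no surviving species at {co2_pal} PAL")
    return species[int(np.argmax(res.species_weights))]


def response_curves(
    species_source: str = "fixture_I",
    co2_range: np.ndarray | None = None,
    par_range: np.ndarray | None = None,
    o2_range: np.ndarray | None = None,
    seed: int = 0,
    temp_c: float = 20.0,
) -> pd.DataFrame:
    """NPP response curves vs CO2, light and O2 at saturated water content.

    ``species_source`` is one of ``fixture_I``, ``fixture_II``,
    ``high_co2_dominant`` (dominant species of a 24 PAL run) or
    ``present_day_dominant`` (dominant species of a 1 PAL run).  NPP is in
    umol CO2 m-2 s-1, the protocol's measurement convention.
    """
    co2_range = np.asarray(
        [200, 400, 700, 1000, 1500, 2240, 4480, 6720] if co2_range is None else co2_range,
        dtype=float,
    )
    par_range = np.asarray(
        [25, 50, 100, 250, 500, 1000] if par_range is None else par_range, dtype=float
    )
    o2_range = np.asarray(
        [0.05, 0.10, 0.14, 0.21, 0.30] if o2_range is None else o2_range, dtype=float
    )
    if co2_range.size == 0 or par_range.size == 0 or o2_range.size == 0:
        raise ValueError("ranges must be non-empty")

    if species_source in FIXTURE_SPECIES:
        sp = FIXTURE_SPECIES[species_source]
    elif species_source == "high_co2_dominant":
        sp = dominant_species(24.0, seed)
    elif species_source == "present_day_dominant":
        sp = dominant_species(1.0, seed)
    else:
        raise ValueError(f"unknown species_source {species_source!r}")

    rows = []

    def npp_umol(par_umol, ca_ppm, o2):
        _, _, npp = net_assimilation(sp, par_umol * 1e-6, temp_c, 1.0, ca_ppm * 1e-6, o2)
        return npp * 1e6

    for ca in co2_range:
        rows.append({"axis": "co2_ppm", "value": ca, "npp_umol": npp_umol(250.0, ca, 0.21)})
    for par in par_range:
        rows.append({"axis": "par_umol", "value": par, "npp_umol": npp_umol(par, 400.0, 0.21)})
    for o2 in o2_range:
        rows.append({"axis": "o2_frac", "value": o2, "npp_umol": npp_umol(250.0, 400.0, o2)})
    out = pd.DataFrame(rows)
    out.insert(0, "species", species_source)
    return out


def _experiment_response_curves(cfg: ExperimentConfig):
    sources = cfg.overrides.get(
        "sources", ("fixture_I", "fixture_II", "high_co2_dominant", "present_day_dominant")
    )
    table = pd.concat(
        [response_curves(s, seed=cfg.seed) for s in sources], ignore_index=True
    )
    return table, {}


# ---------------------------------------------------------------------------
# Dispatch and outputs
# ---------------------------------------------------------------------------

_DISPATCH = {
    "baseline": _experiment_baseline,
    "co2_sweep": _experiment_co2_sweep,
    "species_sweep": _experiment_species_sweep,
    "hirnantian": _experiment_hirnantian,
    "param_sensitivity": _experiment_param_sensitivity,
    "today_reference": _experiment_today_reference,
    "response_curves": _experiment_response_curves,
}


def _config_hash(cfg: ExperimentConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return float(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run a named experiment; optionally write CSV/netCDF/manifest."""
    table, fields = _DISPATCH[cfg.name](cfg)
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "summary.csv", index=False)
        for tag, ds in fields.items():
            cwio.write_netcdf(ds, out / f"{tag}.nc")
        manifest = {
            "experiment": cfg.name,
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
            "overrides": {k: str(v) for k, v in cfg.overrides.items()},
            "outputs": ["summary.csv"] + [f"{t}.nc" for t in fields],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table
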