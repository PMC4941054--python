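"""TOML configuration loading.

One structured file configures the whole pipeline, with sections
``[climate]``, ``[vegetation]``, ``[weathering]`` and ``[experiment]``;
every key is optional and overrides the corresponding dataclass default.

Example::

    [climate]
    n_lon = 32
    n_lat = 16
    land_fraction = 0.25
    temp_sensitivity_per_doubling = 3.0
    seed = 42

    [vegetation]
    n_species = 16
    n_years = 30
    tau_d_years = 100
    co2_pal = 8.0
    o2_fraction = 0.14
    eta_ccm = 8.0

    [weathering]
    cp_mass_ratio = 350.0
    recycling_ratio = 5.0
    p_conc = 1432.0
    soil_pco2_ppm = 10000.0
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import replace
from pathlib import Path

from .carbonate import SoilChemistry
from .climate import ClimateConfig
from .experiments import ExperimentConfig, PipelineConfig
from .vegetation import VegConfig
from .weathering import DEFAULT_K_E, RockGeochem, Stoichiometry


def _apply(dc, section: dict, rename: dict[str, str] | None = None):
    rename = rename or {}
    known = {f.name for f in dataclasses.fields(dc)}
    updates = {}
    for key, val in section.items():
        key = rename.get(key, key)
        if key in known:
            updates[key] = val
    return replace(dc, **updates)


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse a TOML config file into an ExperimentConfig."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    pcfg = PipelineConfig()
    seed = 0

    clim = raw.get("climate", {})
    seed = int(clim.pop("seed", seed))
    for key in ("n_lon", "n_lat", "land_fraction"):
        if key in clim:
            pcfg = replace(pcfg, **{key: clim.pop(key)})
    pcfg = replace(pcfg, climate=_apply(pcfg.climate, clim))

    vegsec = raw.get("vegetation", {})
    if "co2_pal" in vegsec:
        pcfg = replace(pcfg, co2_pal=float(vegsec["co2_pal"]))
    pcfg = replace(
        pcfg,
        veg=_apply(pcfg.veg, vegsec, rename={
            "phi_rr_scale": "phi_rr",  # absolute value if given directly
            "dco2_range_scale": "dco2_scale_high",
        }),
    )

    wsec = dict(raw.get("weathering", {}))
    if "k_e" in wsec:
        pcfg = replace(pcfg, k_e=float(wsec.pop("k_e")))
    if "soil_pco2_ppm" in wsec:
        pcfg = replace(pcfg, soil=replace(pcfg.soil, soil_pco2=float(wsec.pop("soil_pco2_ppm"))))
    pcfg = replace(pcfg, stoich=_apply(pcfg.stoich, wsec), rock=_apply(pcfg.rock, wsec))

    esec = raw.get("experiment", {})
    return ExperimentConfig(
        name=esec.get("name", "baseline"),
        seed=int(esec.get("seed", seed)),
        overrides=esec.get("overrides", {}),
        output_dir=esec.get("output_dir"),
        pipeline=pcfg,
    )
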