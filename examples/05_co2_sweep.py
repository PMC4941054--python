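"""CO2 sensitivity: vegetation-driven vs abiotic weathering.

Sweeps atmospheric CO2 and prints both curves.  The vegetation curve rises
steeply then saturates (Michaelis-Menten photosynthesis); the abiotic curve
keeps climbing because its exponential temperature response compensates the
logarithmic CO2-temperature law — the contrast that makes the biotic
feedback a strong climate stabiliser.
"""

from cryptoweather import ExperimentConfig, PipelineConfig, run_experiment
from cryptoweather.vegetation import VegConfig

cfg = ExperimentConfig(
    name="co2_sweep",
    seed=1,
    overrides={"co2_levels": (3.0, 6.0, 12.0, 24.0)},
    pipeline=PipelineConfig(n_lon=24, n_lat=12, veg=VegConfig(n_species=16, n_years=30)),
)
table = run_experiment(cfg)
print(table.round(3).to_string(index=False))
print("\nbiotic_km3 is realized (limit-capped) weathering by the simulated"
      " vegetation; abiotic_km3 scales today's calcium fluxes to the same"
      " land temperature with the pre-vascular factor 0.25.")
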