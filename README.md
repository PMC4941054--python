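# cryptoweather

Desk-scale simulation of global chemical weathering by early non-vascular
vegetation (lichens and bryophytes) under high-CO2 paleoclimates, with the
abiotic and present-day reference models needed to put that estimate in
context.

Before vascular plants, cryptogamic covers were plausibly the main biotic
agent of rock weathering: they dissolve surface minerals to obtain
phosphorus for growth. This package estimates that flux from first
principles, for whoever wants to experiment with the mechanism — Earth
system modellers, biogeochemists, or anyone curious how a moss-covered
supercontinent could pull down CO2.

## The model

1. **Synthetic climate.** A configurable lat/lon world: a southern-
   hemisphere-weighted supercontinent, monthly climate fields with a wet
   equator, arid ~30° belts and a poleward temperature gradient, and a land
   temperature that shifts by `S · log2(CO2/CO2_ref)` (default S = 3 °C per
   doubling, with extra cooling at low CO2). A stochastic weather generator
   downscales each cell's months to hourly forcing, conserving every
   monthly mean/total to 1e-6.

2. **Trait-sampled vegetation.** Each "species" is a Monte-Carlo draw of a
   physiological parameter vector (Rubisco capacity V_cmax, electron
   transport J_max, Q10 respiration, thallus CO2 diffusivity at saturation
   D_CO2, water storage, optimum temperature). Photosynthesis is the
   Farquhar scheme, A = min(W_c, W_j), evaluated at a chloroplast CO2
   concentration raised by a carbon-concentration mechanism (Cc = η_CCM·ci)
   at an electron cost; ci balances diffusive supply through the wet
   thallus against demand. Hydration is passive (poikilohydry): a bucket
   filled by rain, dew and snowmelt, drained by equilibrium-bound
   evaporation, overflowing as runoff. Species whose NPP = GPP − R cannot
   sustain their biomass die out per cell; survivors are weighted by
   accumulated NPP.

3. **Weathering.** NPP implies a phosphorus demand via the biomass C:P
   ratio (350 g C/g P) and a nutrient recycling ratio (default 5:1); demand
   divided by rock phosphorus content (1,432 g P m⁻³) gives an NPP-based
   weathering flux. Two caps apply cell-wise: the erosion limit
   (fresh-rock exposure, proportional to elevation) and the runoff limit
   (calcium export at calcite equilibrium for the soil pCO2, default
   10,000 ppm). Realized weathering is the minimum of the three, and the
   shortfall feeds back as phosphorus limitation of NPP.

4. **References.** Budyko-curve runoff, the GEM-CO2 runoff–lithology
   model calibrated to present-day calcium fluxes (3.4e12 silicate +
   2.1e12 carbonate = 5.5e12 mol yr⁻¹), and a GEOCARB-III-style scaling of
   abiotic weathering with the pre-vascular biotic factor 0.25.

## Worked example

```bash
python examples/03_weathering_limits.py
```

```
potential NPP       :   28.5 Gt C yr-1
realized  NPP       :    8.8 Gt C yr-1 (69% phosphorus-limited)
GPP                 :   35.2 Gt C yr-1
mean cover          :   0.87
biomass             :    353 Gt C
potential weathering:  11.35 km3 rock yr-1
realized  weathering:   3.51 km3 rock yr-1

limiting factor shares over vegetated cells:
  npp     :   0.0%
  erosion :  80.6%
  runoff  :  19.4%
```

Reading: on this synthetic world at 8 PAL CO2 the vegetation could weather
11 km³ of rock a year if phosphorus demand were the only control, but the
exposure of fresh rock (erosion) and the export capacity of runoff cap the
realized flux at ~3.5 km³ yr⁻¹ — a few km³ yr⁻¹, i.e. several times today's
global chemical weathering — and the phosphorus shortfall cuts realized NPP
accordingly. `examples/05_co2_sweep.py` shows the stabilising contrast:
the biotic curve rises steeply with CO2 and saturates, the abiotic curve
never does.

Other entry points: `examples/01`–`06` cover the synthetic world, a
single-cell stand, the reference models and single-species CO2/light/O2
response curves. The same pipeline is scriptable from a shell:

```bash
cryptoweather run co2_sweep --seed 1 --out runs/sweep
```

## Layout

| Module | What it does |
| --- | --- |
| `grid`, `geography`, `climate`, `downscale` | synthetic world and hourly weather |
| `species`, `physiology`, `hydrology`, `kernel`, `vegetation` | trait sampling, Farquhar/Q10/CCM, water and snow, cell/grid simulation |
| `carbonate`, `weathering` | calcite equilibrium, P-stoichiometry, limits, totals |
| `baselines` | Budyko, GEM-CO2, GEOCARB-style abiotic scaling |
| `experiments`, `config`, `io`, `cli` | named experiments, TOML config, netCDF/CSV output, CLI |

See `docs/methods.md` for the modelling choices, parameter defaults and
their rationale, and the known limitations.
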