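# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, what the synthetic data emulate and do not, the
numerical choices, and the limitations a user should know before trusting
a number.

## Scope and strategy

The package estimates chemical weathering by non-vascular vegetation
(lichens/bryophytes) on a synthetic high-CO2 paleo-world. "Chemical
weathering" means the volume of primary minerals chemically transformed
per time — the quantity that can be compared with an erosion rate. The
pipeline is: synthetic climate → hourly weather → trait-sampled vegetation
→ NPP → phosphorus demand → rock volume, capped by erosion and runoff
limits, with the shortfall fed back as phosphorus limitation of NPP.

Absolute global values depend on the forcing; since the package generates
its own climate rather than using GCM output, absolute results are
indicative, while the structure of the estimate — the limit logic, the
stoichiometric conversions, the CO2 sensitivity, the biotic/abiotic
contrast — is the tested substance.

## Synthetic climate and weather

The world is a regular lat/lon grid (experiments default 32×16; unit tests
8×8) with exact spherical cell areas. Land (default 25% of the globe) is a
smoothed random field biased to a southern supercontinent plus equatorial
landmasses; elevation is a smoothed nonnegative field tapered at coasts,
normalised to a 500 m land mean.

Monthly climate is imposed analytically plus smooth noise: temperature
falls poleward (~36 °C equator-pole contrast at sea level), a seasonal
cycle in hemispheric phase opposition, rainfall with an ITCZ-following
equatorial peak, subtropical minima near ±30°, and mid-latitude storm
tracks. CO2 couples in analytically: land temperature shifts by 3 °C per
doubling around the 8 PAL reference, with an extra quadratic cooling term
below the reference (the log law is known to fail at low CO2 when ocean
dynamics and ice feedbacks kick in), and rainfall scales +4% per degree of
CO2-driven warming. There is no atmospheric dynamics, no ocean, and no
interannual variability: one climatological year, repeated.

The weather generator downscales each cell's 12 monthly values to an
8640-hour year (360-day calendar, 12×30 days — the paleo-GCM convention
that makes monthly bookkeeping exact). States (temperature, humidity,
longwave, wind) get deterministic diurnal cycles whose monthly mean equals
the input exactly (humidity amplitudes are capped so clipping never breaks
the mean); shortwave is a daylight half-sine with day length from latitude
and season; precipitation falls in wet spells with exponential dry/wet
durations and exponential intensities, rescaled so each month's total is
exact. Event statistics are configurable; exact conservation is the
contract the tests enforce.

## Vegetation model

**Trait sampling.** Each artificial species is an independent draw:
log-uniform V_cmax(20 °C) in 0.1–30 µmol m⁻² s⁻¹, J_max = (1.4–2.6)·V_cmax,
Q10 in 1.5–2.5, log-uniform saturated thallus CO2 diffusivity D_CO2 in
3×10⁻⁶–10⁻⁴ m s⁻¹, water storage 1–10 kg m⁻², albedo 0.10–0.30, optimum
temperature 5–30 °C. Two constants are universal rather than sampled,
because they express physiological constraints rather than strategies: the
ratio of photosynthetic capacity to maintenance respiration Φ_RR
(default 30: R_ref = V_cmax/Φ_RR) and the CCM concentration factor η_CCM
(default 8, sweepable 2–45). The D_CO2 range is deliberately low enough
that CO2 supply through the soaked thallus — not biochemistry — limits
assimilation for most species at present-day CO2; that supply limitation
is what makes NPP strongly CO2-sensitive, and Φ_RR = 30 is what lets such
supply-limited, Rubisco-rich species pay their maintenance costs and
survive. These ranges are package choices representative of measured
bryophyte/lichen physiology; they are the knobs to revisit first when
calibrating against data.

**Photosynthesis.** Farquhar scheme: A = min(W_c, W_j) at chloroplast CO2
Cc = η_CCM·ci, with Michaelis constants and the photorespiratory
compensation point (proportional to O2) on standard Arrhenius responses,
and V_cmax/J_max on a peaked response centred at the species' T_opt.
Electron transport follows a non-rectangular hyperbola (α = 0.3 mol e⁻/mol
photons, θ = 0.9); the CCM's electron cost is a logarithmic tax
J_eff = J/(1 + 0.12·ln η_CCM) — concentrating against a gradient costs
energy like ln(concentration factor). The internal ci balances diffusive
supply g(s)·(ca − ci), with g(s) = ρ_air·D_CO2·(1 + 4(1−s)) decreasing in
water saturation s, against A(ci); the residual is monotone, so bisection
on [0, ca] converges unconditionally (40 halvings in the gridded kernel,
48 in the API; ~1e-12–1e-14 relative).

**Water, snow, activity.** The thallus is a bucket: rain + dew (nights
with RH ≥ 0.95) + snowmelt in; evaporation out, bounded by the stored
amount and by equilibrium evaporation s/(s+γ)·R_net/λ scaled by
saturation; overflow above capacity is runoff. Closure is exact by
construction and audited to 1e-9. Snow is a degree-day pack (0.2 mm h⁻¹
K⁻¹) with a small lateral "glacier flow" loss; a cell whose pack still
grows after a full year at a rate above 50 kg m⁻² yr⁻¹ is dynamically
glaciated, and prescribed glacier masks (the Hirnantian scenario: all land
south of 30° S) always override. Metabolism — both photosynthesis and
respiration — runs only when saturation exceeds 10% of capacity
(poikilohydry: dry means dormant) and the cell is not snow-covered.

**Demography and aggregation.** Hourly rates depend on forcing and water
state but not on standing biomass, and the forcing year repeats; the
kernel therefore integrates one year per cell (numba-compiled) and the
multi-year part is an annual recurrence. Species share one canopy: cover_i
= b_i/(Σb + h) with h = 0.2 kg C m⁻², per-ground-area gain =
NPP·cover_i, turnover 0.05 yr⁻¹. Growth from seed (5 g C m⁻²) is
exponential, and dominants suppress marginal species (competitive
exclusion), so the accumulated-NPP weights concentrate on the most
productive trait combinations — this is what makes grid NPP increase with
the number of sampled species (undersampling effect) instead of being
diluted by mediocre survivors. A species dies when its biomass falls below
1% of the seed. Disturbance resets biomass to seed every τ_D years
(default 100): stocks (cover, biomass) collapse under frequent
disturbance while rates (NPP) barely move. Defaults: 16–30 species,
30–50 years; these are the package's desk-scale study conditions, with
larger profiles available via config.

## Weathering

Phosphorus demand = NPP/(C:P) · (1 − resorption + leaching)/r. C:P = 350
g C per g P — chosen so the desert reference (NPP 5 g C m⁻² yr⁻¹,
weathering 0.002 mm yr⁻¹, rock P 1,432 g m⁻³) yields a recycling ratio of
exactly ~5:1, the number `scripts/acceptance.py` recomputes. Resorption
and leaching nearly compensate; the net factor defaults to 1. The
recycling ratio r defaults to 5 (pre-vascular ecosystems without deep
roots or mycorrhiza recycle poorly; modern ecosystems are ~50).

NPP-based weathering = demand / 1,432 g P m⁻³. The erosion limit is
k_e·elevation with k_e = 6×10⁻⁸ yr⁻¹ (1,000 m → 0.06 mm yr⁻¹ denudation).
The runoff limit converts vegetated-area runoff (cell runoff × cover)
times the calcite-equilibrium calcium concentration into rock volume via
the mean rock calcium content. Realized weathering is the cell-wise
minimum; the label tie-break priority is npp > erosion > runoff. Realized
NPP = potential · (realized/NPP-based weathering) where demand is
positive.

The calcite equilibrium solves the open CO2–H2O–CaCO3 system (Henry,
both carbonic-acid dissociations, calcite solubility, water
autoionisation, charge balance) by Brent root-finding on [H+] with 1e-12
relative tolerance, using the standard temperature-dependent constants;
an independent quartic-root oracle agrees to 1e-6 and the ideal
cube-root law [Ca] ∝ pCO2^(1/3) to 1%. Mineral-mix effects are collapsed
into a composition factor (granite 1.15 … shale 0.60) scaling the
pure-calcite solution. Soil pCO2 defaults to 10,000 ppm, a mid-depth
modern soil value and comfortably above a 2,240 ppm atmosphere.

The global calcium-flux ↔ rock-volume conversion uses one calibrated
constant, 7.7×10¹²/1.8×10⁹ ≈ 4,278 mol Ca m⁻³ rock, anchored on the
limit-based present-day pair and cross-checked against the GEM pair
(5.5×10¹² mol → 1.29 ≈ 1.3 km³).

## Reference models

Budyko runoff: PET from equilibrium evaporation; E/P =
√(φ·tanh(1/φ)·(1−e^(−φ))), φ = PET/P; runoff = P − E, provably inside
[max(0, P−PET), P]. GEM-CO2: per-lithology slopes (carbonate ≫ silicate)
normalized so a present-day-like runoff climatology reproduces the
configured component fluxes — the model is used as a scaling reference,
so the normalization, not the absolute slopes, carries the content.
GEOCARB-style abiotic scaling: silicate flux × e^(0.09ΔT)·(1+0.038ΔT)^0.65,
carbonate × (1+0.087ΔT), times uplift, land-area and the pre-vascular
biotic factor 0.25; ΔT comes from the same synthetic climate that drives
the vegetation, so both curves share one CO2→temperature forcing, with
the 1 PAL state as reference.

## What the synthetic data do and do not show

The generator reproduces the statistical structure that matters for the
mechanism (zonal gradients, aridity belts, diurnal/seasonal cycles,
CO2–temperature–rainfall coupling) but not any particular reconstruction:
no real paleogeography, no ocean, no weather regimes, no orographic
rainfall. Passing tests therefore demonstrate that the *method* behaves
as documented — conservation, limits, feedback directions, CO2
saturation, biotic/abiotic contrast — not that any absolute global number
is a prediction for the real Ordovician. Global totals from the default
world land in the right order of magnitude (a few km³ rock yr⁻¹, a few
Gt C yr⁻¹), which is all they are designed to do.

## Numerical choices and degenerate inputs

- 0-based cell indexing, fields on cell centers, ocean masked with NaN in
  vegetation fields and zero flux in totals.
- Master seed → independent substreams per purpose and cell via
  `numpy.random.SeedSequence` spawn keys; identical (inputs, seed) give
  bit-identical outputs, independent of evaluation order.
- Bisection/brentq tolerances as above; monthly conservation enforced by
  exact rescaling rather than by distributional assumptions.
- Degenerate cases: zero monthly precipitation → zero hourly series; a
  polar-night month with nonzero shortwave → uniform distribution; zero
  assimilation demand → ci = ambient; empty survivor set → barren cell,
  excluded from vegetated area; composition factor 0 → zero dissolved
  calcium; zero potential weathering → no phosphorus limitation.
- netCDF output uses the NETCDF3 (scipy) engine with CF-style dims.

## Known limitations

- One climatological year repeated: no interannual variability, so
  survival filtering is sharper than under variable climate.
- Heat balance is simplified to an equilibrium-evaporation bound with
  fixed aerodynamic conductance; no explicit surface-energy iteration.
- Per-area physiological rates are biomass-independent; canopy
  self-shading and within-stand microclimate are not represented.
- The CCM electron tax and the D(saturation) shape are one-parameter
  families standing in for unpublished functional forms; both are
  config-exposed.
- No nitrogen cycle; weathering-agent secretion costs are assumed folded
  into measured respiration. No per-element budgets and no kinetic rate
  laws: the limit-based approach presumes reaction kinetics are rarely
  the global bottleneck, which fails in some humid mountain settings.
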