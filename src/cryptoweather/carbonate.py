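"""Open-system calcite equilibrium: dissolved Ca2+ at a given soil pCO2.

Solves the CO2-H2O-CaCO3 speciation (Henry dissolution, the two carbonic
acid dissociations, calcite solubility and water autoionisation) subject to
charge balance 2[Ca] + [H] = [HCO3] + 2[CO3] + [OH], by root-finding on
[H+].  Equilibrium constants use the standard temperature-dependent
analytic expressions (Plummer & Busenberg 1982).  In the dilute ideal
limit the solution follows the classic cube-root law
[Ca] ~ (K1*KH*Ksp*pCO2 / (4*K2))^(1/3).

A dimensionless composition factor scales the result for soils whose
mineral mix is more (granite-like) or less (shale-like) productive of
dissolved calcium than pure calcite substrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: Relative Ca yield of the six lithology classes against the mean (=1.0).
COMPOSITION_FACTORS: dict[str, float] = {
    "granite": 1.15,
    "basalt": 1.05,
    "limestone": 1.10,
    "sandstone": 0.75,
    "rhyolite": 0.85,
    "shale": 0.60,
}


@dataclass
class SoilChemistry:
    """Soil solution boundary conditions for the calcite equilibrium."""

    soil_pco2: float = 10_000.0      # ppm; at least the atmospheric level
    temperature: float = 15.0        # degC
    composition_factor: float = 1.0  # relative activity of Ca-bearing minerals


def _log10_constants(t_c: float) -> tuple[float, float, float, float]:
    """(log10 KH, log10 K1, log10 K2, log10 Ksp_calcite) at temperature."""
    t = t_c + 273.15
    lg = np.log10(t)
    log_kh = 108.3865 + 0.01985076 * t - 6919.53 / t - 40.45154 * lg + 669365.0 / t**2
    log_k1 = -356.3094 - 0.06091964 * t + 21834.37 / t + 126.8339 * lg - 1684915.0 / t**2
    log_k2 = -107.8871 - 0.03252849 * t + 5151.79 / t + 38.92561 * lg - 563713.9 / t**2
    log_ksp = -171.9065 - 0.077993 * t + 2839.319 / t + 71.595 * lg
    return log_kh, log_k1, log_k2, log_ksp


def calcite_equilibrium_ca(soil: SoilChemistry) -> float:
    """Equilibrium dissolved calcium (mol per m3 of water).

    Raises ``ValueError`` for nonpositive pCO2 and ``RuntimeError`` when
    the root-finder cannot bracket a solution.
    """
    if soil.soil_pco2 <= 0:
        raise ValueError(f"soil_pco2 must be positive, got {soil.soil_pco2}")
    if soil.composition_factor == 0.0:
        return 0.0  # no Ca-bearing minerals

    log_kh, log_k1, log_k2, log_ksp = _log10_constants(soil.temperature)
    kh, k1, k2, ksp = (10.0**x for x in (log_kh, log_k1, log_k2, log_ksp))
    kw = 1.0e-14
    p_atm = soil.soil_pco2 * 1e-6  # ppm -> atm

    co2_aq = kh * p_atm

    def charge_imbalance(h: float) -> float:
        hco3 = k1 * co2_aq / h
        co3 = k2 * hco3 / h
        ca = ksp / co3
        oh = kw / h
        return 2.0 * ca + h - hco3 - 2.0 * co3 - oh

    try:
        h = brentq(charge_imbalance, 1e-14, 1e-2, xtol=1e-18, rtol=1e-12)
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError("calcite equilibrium: no root in bracket") from exc

    co3 = k1 * k2 * co2_aq / h**2
    ca_mol_l = ksp / co3
    return float(soil.composition_factor * ca_mol_l * 1000.0)  # mol m-3
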