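"""Photosynthesis and respiration physiology.

Gross assimilation follows the Farquhar scheme: the minimum of the
Rubisco-limited rate Wc and the electron-transport-limited rate Wj,
evaluated at the chloroplast CO2 concentration Cc.  A carbon-concentration
mechanism (CCM) raises Cc = eta_ccm * ci above the internal concentration
ci at an electron cost, modelled as a logarithmic tax on the electron
transport rate (concentrating against a gradient costs energy ~ ln eta).
Michaelis constants and the photorespiratory compensation point follow
standard Arrhenius temperature responses; Vcmax and Jmax use a peaked
response centred on the species' optimum temperature.

ci itself is set by balancing diffusive CO2 supply through the (wet)
thallus against assimilation demand; diffusivity decreases with water
saturation, reaching its species-specific minimum d_co2_sat when soaked.

Respiration is a Q10 law anchored at 20 degC, with the reference rate tied
to photosynthetic capacity through the universal ratio phi_rr.

The scalar kernels are numba-compiled so the gridded simulator can call
them millions of times; the public functions accept SpeciesParams.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .species import T_REF_C, SpeciesParams

R_GAS = 8.314462618  # J mol-1 K-1
AIR_MOLAR_DENSITY = 41.6  # mol m-3 at surface pressure

# Michaelis-Menten / compensation-point parameters at 25 degC (mol mol-1)
# with Arrhenius activation energies (J mol-1); standard C3 biochemistry.
KC_25 = 404.9e-6
KC_HA = 79430.0
KO_25 = 278.4e-3
KO_HA = 36380.0
GSTAR_25_PER_O2 = 42.75e-6 / 0.21  # compensation point scales with O2
GSTAR_HA = 37830.0

VJ_HA = 50000.0       # activation energy of Vcmax/Jmax
VJ_HD = 200000.0      # deactivation energy (peaked response)
ALPHA_E = 0.3         # mol e- per mol photons
THETA_J = 0.9         # curvature of the light response
CCM_COST = 0.12       # electron tax coefficient per ln(eta_ccm)

#: Thallus diffusivity multiplier when fully dry relative to saturated.
D_DRY_MULT = 5.0
D_SAT_EXPONENT = 1.0


@njit(cache=True)
def _arrhenius(k_ref: float, ha: float, t_k: float, t_ref_k: float) -> float:
    return k_ref * np.exp(ha / R_GAS * (1.0 / t_ref_k - 1.0 / t_k))


@njit(cache=True)
def _peaked_temp_factor(t_c: float, t_opt_c: float) -> float:
    """Peaked Arrhenius factor, = 1 at T_REF_C, maximal at t_opt_c."""
    t_k = t_c + 273.15
    t_ref = T_REF_C + 273.15
    t_opt = t_opt_c + 273.15
    # Entropy term chosen so the peak sits at t_opt (Medlyn-style).
    s = VJ_HD / t_opt + R_GAS * np.log(VJ_HA / (VJ_HD - VJ_HA))
    num = np.exp(VJ_HA / R_GAS * (1.0 / t_ref - 1.0 / t_k))
    den = (1.0 + np.exp((s * t_k - VJ_HD) / (R_GAS * t_k))) / (
        1.0 + np.exp((s * t_ref - VJ_HD) / (R_GAS * t_ref))
    )
    return num / den


@njit(cache=True)
def _farquhar(
    vcmax_ref: float,
    jmax_ref: float,
    t_opt: float,
    eta_ccm: float,
    par: float,
    temp_c: float,
    ci: float,
    o2: float,
) -> float:
    """Gross assimilation (mol CO2 m-2 s-1), clipped at zero."""
    if par <= 0.0 or ci <= 0.0:
        return 0.0
    t_k = temp_c + 273.15
    t_ref_k = 298.15
    kc = _arrhenius(KC_25, KC_HA, t_k, t_ref_k)
    ko = _arrhenius(KO_25, KO_HA, t_k, t_ref_k)
    gstar = _arrhenius(GSTAR_25_PER_O2 * o2, GSTAR_HA, t_k, t_ref_k)

    f_t = _peaked_temp_factor(temp_c, t_opt)
    vcmax = vcmax_ref * f_t
    jmax = jmax_ref * f_t

    cc = eta_ccm * ci
    if cc <= gstar:
        return 0.0

    wc = vcmax * (cc - gstar) / (cc + kc * (1.0 + o2 / ko))

    # Non-rectangular hyperbola for electron transport, then the CCM tax.
    ij = ALPHA_E * par
    disc = (ij + jmax) ** 2 - 4.0 * THETA_J * ij * jmax
    j = (ij + jmax - np.sqrt(max(disc, 0.0))) / (2.0 * THETA_J)
    j_eff = j / (1.0 + CCM_COST * np.log(eta_ccm))
    wj = j_eff * (cc - gstar) / (4.0 * cc + 8.0 * gstar)

    a = min(wc, wj)
    return a if a > 0.0 else 0.0


@njit(cache=True)
def _diffusivity(d_co2_sat: float, saturation: float) -> float:
    """Thallus CO2 diffusivity (m s-1); decreases with water saturation."""
    s = min(max(saturation, 0.0), 1.0)
    return d_co2_sat * (1.0 + (D_DRY_MULT - 1.0) * (1.0 - s) ** D_SAT_EXPONENT)


@njit(cache=True)
def _solve_ci(
    vcmax_ref: float,
    jmax_ref: float,
    t_opt: float,
    eta_ccm: float,
    d_co2_sat: float,
    saturation: float,
    par: float,
    temp_c: float,
    ambient: float,
    o2: float,
    n_iter: int,
) -> float:
    """Internal CO2 where diffusive supply equals assimilation demand.

    Supply g*(ca - ci) is decreasing in ci, demand A(ci) non-decreasing, so
    the residual is monotone and bisection on [0, ca] converges; n_iter
    halvings give a relative precision of 2^-n_iter.
    """
    g = _diffusivity(d_co2_sat, saturation) * AIR_MOLAR_DENSITY
    lo = 0.0
    hi = ambient
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        resid = g * (ambient - mid) - _farquhar(
            vcmax_ref, jmax_ref, t_opt, eta_ccm, par, temp_c, mid, o2
        )
        if resid > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def farquhar_gpp(
    params: SpeciesParams, par: float, temp: float, ci: float, o2: float
) -> float:
    """Gross assimilation rate (mol CO2 m-2 s-1) at a given internal CO2.

    par is photosynthetically active radiation in mol photons m-2 s-1; ci
    and o2 are mole fractions (mol mol-1).
    """
    if par < 0 or ci < 0 or o2 < 0:
        raise ValueError("par, ci and o2 must be nonnegative")
    return float(
        _farquhar(params.vcmax_ref, params.jmax_ref, params.t_opt,
                  params.eta_ccm, par, temp, ci, o2)
    )


def respiration(params: SpeciesParams, temp: float) -> float:
    """Maintenance respiration (mol CO2 m-2 s-1) via the Q10 law."""
    return float(params.resp_ref * params.q10 ** ((temp - T_REF_C) / 10.0))


def internal_co2(
    params: SpeciesParams,
    saturation: float,
    ambient_co2: float,
    assimilation_demand: float,
) -> float:
    """Internal CO2 (mol mol-1) supporting a fixed assimilation demand.

    With zero demand there is no gradient and ci equals the ambient
    concentration; the result is floored at zero when the demand exceeds
    what diffusion can supply.
    """
    if not 0.0 <= saturation <= 1.0:
        raise ValueError("saturation must be in [0, 1]")
    g = _diffusivity(params.d_co2_sat, saturation) * AIR_MOLAR_DENSITY
    return float(max(0.0, ambient_co2 - assimilation_demand / g))


def net_assimilation(
    params: SpeciesParams,
    par: float,
    temp: float,
    saturation: float,
    ambient_co2: float,
    o2: float,
    n_iter: int = 48,
) -> tuple[float, float, float]:
    """Solve the consistent (ci, GPP) pair and return (ci, gpp, npp).

    npp = gpp - respiration; all rates mol CO2 m-2 s-1.
    """
    if par < 0 or ambient_co2 < 0 or o2 < 0:
        raise ValueError("par, ambient_co2 and o2 must be nonnegative")
    ci = _solve_ci(
        params.vcmax_ref, params.jmax_ref, params.t_opt, params.eta_ccm,
        params.d_co2_sat, saturation, par, temp, ambient_co2, o2, n_iter,
    )
    gpp = farquhar_gpp(params, par, temp, ci, o2)
    return float(ci), gpp, gpp - respiration(params, temp)
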