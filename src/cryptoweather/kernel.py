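"""Numba kernel integrating one forcing year, hour by hour, per species.

Hourly physiological rates depend on the forcing and on the water/snow
state but not on standing biomass, and the forcing year repeats, so a
single hourly integration of the year yields each species' annual GPP,
respiration, NPP and runoff; the multi-year demography (biomass, survival,
disturbance) is then an annual recurrence handled in
:mod:`cryptoweather.vegetation`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .hydrology import SNOW_COVER_SWE, _snow_update, _water_update
from .physiology import _farquhar, _solve_ci
from .species import T_REF_C

CI_BISECT_ITER = 40


@njit(cache=True)
def simulate_forcing_year(
    sw: np.ndarray,
    lw: np.ndarray,
    rain: np.ndarray,
    snowfall: np.ndarray,
    temp: np.ndarray,
    rh: np.ndarray,
    vcmax_ref: np.ndarray,
    jmax_ref: np.ndarray,
    q10: np.ndarray,
    resp_ref: np.ndarray,
    d_co2_sat: np.ndarray,
    theta_max: np.ndarray,
    albedo: np.ndarray,
    t_opt: np.ndarray,
    eta_ccm: float,
    ambient_co2: float,
    o2: float,
    activity_threshold: float,
    par_per_sw: float,
    init_saturation: float,
):
    """Integrate one 8640-h year for all species of one cell.

    Returns per-species annual (gpp_mol, resp_mol, npp_mol, runoff_mm,
    active_hours) plus the cell snowpack's (swe_end, swe_max,
    snowcovered_hours).  Units: mol CO2 m-2 yr-1 and mm yr-1.
    """
    n_hours = sw.shape[0]
    n_sp = vcmax_ref.shape[0]

    gpp = np.zeros(n_sp)
    resp = np.zeros(n_sp)
    runoff = np.zeros(n_sp)
    active_hours = np.zeros(n_sp)
    storage = init_saturation * theta_max

    swe = 0.0
    swe_max = 0.0
    snowcov_hours = 0.0

    for h in range(n_hours):
        swe, melt = _snow_update(swe, snowfall[h], temp[h])
        if swe > swe_max:
            swe_max = swe
        covered = swe > SNOW_COVER_SWE
        if covered:
            snowcov_hours += 1.0

        for k in range(n_sp):
            storage[k], ro, dew, evap = _water_update(
                storage[k], theta_max[k], rain[h], melt,
                sw[h], lw[h], temp[h], rh[h], albedo[k],
            )
            runoff[k] += ro
            if covered:
                continue  # dormant under snow: no gas exchange
            sat = storage[k] / theta_max[k]
            if sat < activity_threshold:
                continue  # metabolically inactive when dry
            r = resp_ref[k] * q10[k] ** ((temp[h] - T_REF_C) / 10.0)
            resp[k] += r * 3600.0
            active_hours[k] += 1.0
            par = sw[h] * par_per_sw
            if par > 0.0:
                ci = _solve_ci(
                    vcmax_ref[k], jmax_ref[k], t_opt[k], eta_ccm,
                    d_co2_sat[k], sat, par, temp[h], ambient_co2, o2,
                    CI_BISECT_ITER,
                )
                a = _farquhar(
                    vcmax_ref[k], jmax_ref[k], t_opt[k], eta_ccm,
                    par, temp[h], ci, o2,
                )
                gpp[k] += a * 3600.0

    npp = gpp - resp
    return gpp, resp, npp, runoff, active_hours, swe, swe_max, snowcov_hours
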