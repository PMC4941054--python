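"""Monte-Carlo sampling of artificial lichen/bryophyte species.

Instead of fixed plant functional types, the vegetation model draws each
"species" as an independent random vector of physiological parameters.
Rate constants are sampled log-uniformly, bounded traits uniformly.  The
ratio of photosynthetic capacity to maintenance respiration (phi_rr) and
the carbon-concentration-mechanism factor (eta_ccm) are universal
physiological constraints and therefore shared by all species in a
simulation; thallus CO2 diffusivity at saturation is species-specific.

The default ranges are package choices representative of measured
bryophyte/lichen physiology (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: (low, high, scale) for each sampled trait; scale is "log" or "linear".
DEFAULT_RANGES: dict[str, tuple[float, float, str]] = {
    # Rubisco carboxylation capacity at 20 degC, mol CO2 m-2 s-1
    "vcmax_ref": (1.0e-7, 3.0e-5, "log"),
    # Electron transport capacity as a multiple of vcmax_ref
    "jv_ratio": (1.4, 2.6, "linear"),
    # Respiration temperature sensitivity
    "q10": (1.5, 2.5, "linear"),
    # Thallus CO2 diffusivity at full water saturation, m s-1.  Low enough
    # that CO2 supply through the soaked thallus, not biochemistry, limits
    # assimilation for most species at present-day CO2.
    "d_co2_sat": (3.0e-6, 1.0e-4, "log"),
    # Water storage capacity, kg H2O m-2
    "theta_max": (1.0, 10.0, "linear"),
    # Surface albedo
    "albedo": (0.10, 0.30, "linear"),
    # Optimum temperature of photosynthesis, degC
    "t_opt": (5.0, 30.0, "linear"),
}

#: Universal (non-sampled) physiological constants, overridable per run.
#: phi_rr is high enough that strongly diffusion-limited species — whose
#: realized assimilation sits well below their Rubisco capacity — can still
#: pay their maintenance respiration and survive.
DEFAULT_PHI_RR = 30.0
DEFAULT_ETA_CCM = 8.0

T_REF_C = 20.0  # reference temperature for vcmax, jmax and Q10 respiration


@dataclass(frozen=True)
class SpeciesParams:
    """One artificial species' physiological parameter vector."""

    vcmax_ref: float   # mol CO2 m-2 s-1 at T_REF_C
    jmax_ref: float    # mol e- m-2 s-1 at T_REF_C
    q10: float
    phi_rr: float      # Rubisco capacity : maintenance respiration (global)
    d_co2_sat: float   # m s-1 (minimum diffusivity, at full saturation)
    eta_ccm: float     # CCM concentration factor (global)
    theta_max: float   # kg H2O m-2
    albedo: float
    t_opt: float       # degC

    @property
    def resp_ref(self) -> float:
        """Maintenance respiration at T_REF_C, tied to vcmax via phi_rr."""
        return self.vcmax_ref / self.phi_rr

    def __post_init__(self):
        for name in ("vcmax_ref", "jmax_ref", "q10", "phi_rr", "d_co2_sat",
                     "eta_ccm", "theta_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def sample_species(
    n: int,
    ranges: dict[str, tuple[float, float, str]] | None = None,
    seed: int = 0,
    phi_rr: float = DEFAULT_PHI_RR,
    eta_ccm: float = DEFAULT_ETA_CCM,
) -> list[SpeciesParams]:
    """Draw ``n`` artificial species, deterministically for a given seed.

    Each trait is drawn independently from its (low, high) range, uniformly
    on a log scale for rate constants and linearly otherwise.  Degenerate
    ranges (low == high) collapse to that value; low > high or nonpositive
    log-scale bounds raise ``ValueError``.
    """
    if n < 1:
        raise ValueError("need at least one species")
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(41,)))

    draws: dict[str, np.ndarray] = {}
    for name, (lo, hi, scale) in ranges.items():
        if not np.isfinite([lo, hi]).all() or lo > hi:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if scale == "log":
            if lo <= 0:
                raise ValueError(f"log-scale range for {name} must be positive")
            draws[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        else:
            draws[name] = rng.uniform(lo, hi, size=n)

    out = []
    for i in range(n):
        vc = float(draws["vcmax_ref"][i])
        out.append(
            SpeciesParams(
                vcmax_ref=vc,
                jmax_ref=vc * float(draws["jv_ratio"][i]),
                q10=float(draws["q10"][i]),
                phi_rr=phi_rr,
                d_co2_sat=float(draws["d_co2_sat"][i]),
                eta_ccm=eta_ccm,
                theta_max=float(draws["theta_max"][i]),
                albedo=float(draws["albedo"][i]),
                t_opt=float(draws["t_opt"][i]),
            )
        )
    return out


def scaled_dco2_ranges(scale_high: float = 1.0, scale_low: float = 1.0) -> dict:
    """Default ranges with the d_co2_sat bounds rescaled (sensitivity sweeps)."""
    r = dict(DEFAULT_RANGES)
    lo, hi, sc = r["d_co2_sat"]
    r["d_co2_sat"] = (lo * scale_low, hi * scale_high, sc)
    return r


def species_arrays(species: list[SpeciesParams]) -> dict[str, np.ndarray]:
    """Pack a species list into flat float64 arrays for the numeric kernel."""
    return {
        name: np.array([getattr(s, name) for s in species], dtype=np.float64)
        for name in ("vcmax_ref", "jmax_ref", "q10", "d_co2_sat",
                     "theta_max", "albedo", "t_opt")
    } | {
        "resp_ref": np.array([s.resp_ref for s in species], dtype=np.float64),
    }


def with_phi_rr_scale(species: list[SpeciesParams], factor: float) -> list[SpeciesParams]:
    """Rescale the universal phi_rr of every species by ``factor``."""
    return [replace(s, phi_rr=s.phi_rr * factor) for s in species]
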