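"""Species sampling and the photosynthesis/respiration kernels."""

import numpy as np
import pytest

from cryptoweather.physiology import (
    AIR_MOLAR_DENSITY,
    farquhar_gpp,
    internal_co2,
    net_assimilation,
    respiration,
    _diffusivity,
)
from cryptoweather.species import (
    DEFAULT_RANGES,
    SpeciesParams,
    sample_species,
    scaled_dco2_ranges,
)


@pytest.fixture(scope="module")
def sp():
    return SpeciesParams(
        vcmax_ref=1e-5, jmax_ref=2e-5, q10=2.0, phi_rr=30.0,
        d_co2_sat=3e-5, eta_ccm=8.0, theta_max=5.0, albedo=0.2, t_opt=20.0,
    )


class TestSampling:
    def test_count_and_distinctness(self):
        species = sample_species(300, seed=0)
        assert len(species) == 300
        assert len({s.vcmax_ref for s in species}) == 300

    def test_deterministic(self):
        a = sample_species(10, seed=42)
        b = sample_species(10, seed=42)
        assert a == b

    def test_degenerate_ranges_collapse(self):
        ranges = {k: (lo, lo, sc) for k, (lo, hi, sc) in DEFAULT_RANGES.items()}
        species = sample_species(5, ranges=ranges, seed=1)
        assert len({s.d_co2_sat for s in species}) == 1

    def test_universal_constants_shared(self):
        species = sample_species(20, seed=3, phi_rr=12.0, eta_ccm=5.0)
        assert {s.phi_rr for s in species} == {12.0}
        assert {s.eta_ccm for s in species} == {5.0}

    def test_doubling_dco2_upper_bound_raises_sampled_maximum(self):
        base = max(s.d_co2_sat for s in sample_species(10_000, seed=7))
        wide = max(
            s.d_co2_sat
            for s in sample_species(10_000, ranges=scaled_dco2_ranges(scale_high=2.0), seed=7)
        )
        hi = DEFAULT_RANGES["d_co2_sat"][1]
        assert base <= hi < wide <= 2 * hi

    def test_invalid_range_rejected(self):
        bad = dict(DEFAULT_RANGES)
        bad["q10"] = (2.5, 1.5, "linear")
        with pytest.raises(ValueError):
            sample_species(3, ranges=bad, seed=0)


class TestFarquhar:
    def test_no_light_no_assimilation(self, sp):
        assert farquhar_gpp(sp, 0.0, 20.0, 400e-6, 0.21) == 0.0

    def test_compensation_point(self, sp):
        # chloroplast CO2 at the photorespiratory compensation point: no net
        # carboxylation, so the gross rate clips to zero
        gstar_approx = 42.75e-6
        ci = gstar_approx / sp.eta_ccm
        assert farquhar_gpp(sp, 250e-6, 25.0, ci * 0.999, 0.21) == 0.0

    def test_monotone_saturating_in_ci(self, sp):
        ci = np.linspace(1e-6, 8000e-6, 200)
        a = np.array([farquhar_gpp(sp, 250e-6, 20.0, c, 0.21) for c in ci])
        assert (np.diff(a) >= -1e-18).all()
        high = a[ci > 1000e-6]
        assert (np.diff(high, 2) <= 1e-12).all()  # concave at high ci
        assert a[-1] > 0 and np.isfinite(a[-1])

    def test_low_o2_boosts_assimilation(self, sp):
        a21 = farquhar_gpp(sp, 250e-6, 20.0, 300e-6, 0.21)
        a14 = farquhar_gpp(sp, 250e-6, 20.0, 300e-6, 0.14)
        assert a14 > a21

    def test_rejects_negative_inputs(self, sp):
        with pytest.raises(ValueError):
            farquhar_gpp(sp, -1.0, 20.0, 400e-6, 0.21)


class TestRespiration:
    def test_reference_point_and_q10(self, sp):
        assert respiration(sp, 20.0) == pytest.approx(sp.resp_ref)
        assert respiration(sp, 30.0) == pytest.approx(sp.q10 * sp.resp_ref)

    def test_doubling_phi_rr_halves_respiration(self, sp):
        import dataclasses

        doubled = dataclasses.replace(sp, phi_rr=2 * sp.phi_rr)
        assert respiration(doubled, 20.0) == pytest.approx(0.5 * respiration(sp, 20.0))


class TestInternalCO2:
    def test_zero_demand_gives_ambient(self, sp):
        assert internal_co2(sp, 1.0, 400e-6, 0.0) == pytest.approx(400e-6)

    def test_wetter_thallus_lower_ci_at_equal_demand(self, sp):
        demand = 1e-7
        ci_wet = internal_co2(sp, 1.0, 400e-6, demand)
        ci_half = internal_co2(sp, 0.5, 400e-6, demand)
        assert ci_wet < ci_half
        assert _diffusivity(sp.d_co2_sat, 1.0) == pytest.approx(sp.d_co2_sat)

    def test_doubling_ambient_raises_ci(self, sp):
        demand = 1e-7
        assert internal_co2(sp, 1.0, 800e-6, demand) > internal_co2(sp, 1.0, 400e-6, demand)

    def test_consistent_pair_matches_bruteforce(self, sp):
        """The bisection solution balances supply and demand to <=1e-9 rel."""
        ci, gpp, _ = net_assimilation(sp, 250e-6, 20.0, 1.0, 2240e-6, 0.14)
        supply = sp.d_co2_sat * AIR_MOLAR_DENSITY * (2240e-6 - ci)
        assert supply == pytest.approx(gpp, rel=1e-6, abs=1e-15)
        # brute force on a dense ci grid finds the same crossing
        grid = np.linspace(0, 2240e-6, 20001)
        resid = [
            sp.d_co2_sat * AIR_MOLAR_DENSITY * (2240e-6 - c)
            - farquhar_gpp(sp, 250e-6, 20.0, c, 0.14)
            for c in grid
        ]
        crossing = grid[np.searchsorted(-np.array(resid), 0.0)]
        assert ci == pytest.approx(crossing, abs=2 * (grid[1] - grid[0]))


class TestNetAssimilationCO2Response:
    def test_monotone_and_saturating_in_ambient_co2(self, sp):
        ca = np.linspace(100e-6, 10000e-6, 60)
        npp = np.array([net_assimilation(sp, 250e-6, 20.0, 1.0, c, 0.14)[2] for c in ca])
        assert (np.diff(npp) >= -1e-15).all()
        # saturation: the last slope is a small fraction of the first
        first = npp[1] - npp[0]
        last = npp[-1] - npp[-2]
        assert last < 0.2 * first
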