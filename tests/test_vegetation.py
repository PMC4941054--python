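"""Cell/grid vegetation simulation: survival, weights, disturbance, CO2."""

import dataclasses

import numpy as np
import pytest

from cryptoweather.downscale import downscale_to_hourly
from cryptoweather.species import SpeciesParams, sample_species
from cryptoweather.vegetation import VegConfig, run_cell, run_grid


def _doomed_species():
    """Respiration far above any possible assimilation: guaranteed death."""
    return SpeciesParams(
        vcmax_ref=6e-5, jmax_ref=1.2e-4, q10=2.0, phi_rr=1e-3,  # resp = 1000x vcmax
        d_co2_sat=3e-6, eta_ccm=8.0, theta_max=5.0, albedo=0.2, t_opt=20.0,
    )


class TestRunCell:
    def test_doomed_species_dies(self, species_pool, humid_forcing, veg_cfg):
        species = species_pool + [_doomed_species()]
        res = run_cell(species, humid_forcing, veg_cfg)
        assert res.species_weights[-1] == 0.0
        assert res.n_survivors < len(species)

    def test_weights_sum_to_one(self, species_pool, humid_forcing, veg_cfg):
        res = run_cell(species_pool, humid_forcing, veg_cfg)
        assert res.n_survivors > 0
        assert res.species_weights.sum() == pytest.approx(1.0)

    def test_gpp_at_least_npp_and_cover_bounded(self, species_pool, humid_forcing, veg_cfg):
        res = run_cell(species_pool, humid_forcing, veg_cfg)
        assert res.gpp >= res.potential_npp
        assert 0.0 <= res.cover <= 1.0

    def test_deterministic(self, species_pool, humid_forcing, veg_cfg):
        a = run_cell(species_pool, humid_forcing, veg_cfg)
        b = run_cell(species_pool, humid_forcing, veg_cfg)
        assert a.potential_npp == b.potential_npp
        np.testing.assert_array_equal(a.species_weights, b.species_weights)

    def test_frequent_disturbance_cuts_cover_and_biomass_not_npp(
        self, species_pool, humid_forcing
    ):
        often = run_cell(species_pool, humid_forcing, VegConfig(n_years=50, tau_d_years=10))
        rare = run_cell(species_pool, humid_forcing, VegConfig(n_years=50, tau_d_years=250))
        assert often.biomass < 0.7 * rare.biomass
        assert often.cover < rare.cover
        # per-area NPP is a rate: much less affected than the stocks
        assert often.potential_npp == pytest.approx(rare.potential_npp, rel=0.2)

    def test_prescribed_glacier_excludes_vegetation(self, species_pool, humid_forcing, veg_cfg):
        res = run_cell(species_pool, humid_forcing, veg_cfg, prescribed_glacier=True)
        assert res.glaciated and res.potential_npp == 0.0 and res.n_survivors == 0

    def test_empty_forcing_rejected(self, species_pool, humid_forcing, veg_cfg):
        empty = dataclasses.replace(
            humid_forcing,
            **{f: np.empty(0) for f in (
                "shortwave_down", "longwave_down", "rainfall", "snowfall",
                "air_temperature", "wind_speed", "relative_humidity")},
        )
        with pytest.raises(ValueError):
            run_cell(species_pool, empty, veg_cfg)


class TestCO2Response:
    def test_cell_npp_monotone_in_co2(self, species_pool, humid_forcing):
        pals = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
        npp = []
        for pal in pals:
            cfg = VegConfig(n_years=20, co2_pal=pal)
            npp.append(run_cell(species_pool, humid_forcing, cfg).potential_npp)
        assert (np.diff(npp) >= -1e-9).all()

    def test_fixed_species_npp_saturates_in_co2(self, humid_forcing):
        """For one fixed species the annual NPP gain per CO2 doubling
        shrinks once diffusive supply overtakes the biochemical capacity."""
        sp = SpeciesParams(
            vcmax_ref=1e-5, jmax_ref=2e-5, q10=2.0, phi_rr=30.0,
            d_co2_sat=1e-4, eta_ccm=8.0, theta_max=5.0, albedo=0.2, t_opt=25.0,
        )
        npp = []
        for pal in (1.0, 2.0, 4.0, 8.0, 16.0, 32.0):
            cfg = VegConfig(n_years=20, co2_pal=pal)
            npp.append(run_cell([sp], humid_forcing, cfg).potential_npp)
        assert (np.diff(npp) >= -1e-9).all()
        assert (npp[-1] - npp[-2]) < 0.5 * (npp[1] - npp[0]) + 1e-12

    def test_high_co2_selects_higher_photosynthetic_capacity(self, humid_forcing):
        """The dominant survivor under high CO2 has vcmax >= the dominant
        survivor under low CO2 in most paired random pools."""
        wins = 0
        n_rep = 5
        for rep in range(n_rep):
            pool = sample_species(15, seed=100 + rep)
            lo = run_cell(pool, humid_forcing, VegConfig(n_years=20, co2_pal=1.0))
            hi = run_cell(pool, humid_forcing, VegConfig(n_years=20, co2_pal=24.0))
            if lo.n_survivors == 0 or hi.n_survivors == 0:
                continue
            v_lo = pool[int(np.argmax(lo.species_weights))].vcmax_ref
            v_hi = pool[int(np.argmax(hi.species_weights))].vcmax_ref
            wins += v_hi >= v_lo
        assert wins >= 0.8 * n_rep


class TestRunGrid:
    def test_all_glaciated_domain_zero_npp(self, paleo8, climate8, species_pool, veg_cfg):
        frozen = dataclasses.replace(
            paleo8, glacier_mask=paleo8.land_mask.copy(), scenario_tag="hirnantian_ice"
        )
        v = run_grid(frozen, climate8, veg_cfg, seed=1, species=species_pool)
        land_npp = v.potential_npp[paleo8.land_mask]
        assert np.nansum(land_npp) == 0.0
        assert not v.vegetated_mask.any()

    def test_equatorial_npp_exceeds_polar(self, paleo8, climate8, species_pool, veg_cfg):
        v = run_grid(paleo8, climate8, veg_cfg, seed=1, species=species_pool)
        lat = np.abs(paleo8.grid.lat_field)
        trop = v.vegetated_mask & (lat < 30)
        pole = paleo8.land_mask & (lat > 60)
        assert trop.any()
        trop_npp = np.nanmean(v.potential_npp[trop])
        pole_npp = np.nanmean(np.nan_to_num(v.potential_npp[pole])) if pole.any() else 0.0
        assert trop_npp > pole_npp

    def test_grid_mismatch_rejected(self, paleo8, climate8, veg_cfg):
        from cryptoweather.geography import generate_paleogeography
        from cryptoweather.grid import make_grid

        other = generate_paleogeography(make_grid(4, 4), seed=0)
        with pytest.raises(ValueError):
            run_grid(other, climate8, veg_cfg, seed=1)

    def test_deterministic_across_reruns(self, paleo8, climate8, species_pool, veg_cfg):
        a = run_grid(paleo8, climate8, veg_cfg, seed=9, species=species_pool)
        b = run_grid(paleo8, climate8, veg_cfg, seed=9, species=species_pool)
        np.testing.assert_array_equal(a.potential_npp, b.potential_npp)
        np.testing.assert_array_equal(a.runoff, b.runoff)


def test_species_count_monotonicity(paleo8, climate8):
    """Expected grid NPP does not decrease with pool size (nested pools,
    paired seeds): richer pools are more likely to contain high-NPP trait
    combinations."""
    pool = sample_species(80, seed=77)
    totals = []
    for n in (5, 20, 80):
        cfg = VegConfig(n_species=n, n_years=20)
        v = run_grid(paleo8, climate8, cfg, seed=77, species=pool[:n])
        a = paleo8.grid.cell_area
        totals.append(np.nansum(np.where(v.vegetated_mask, v.potential_npp, 0.0) * a))
    assert totals[0] <= totals[1] * 1.02
    assert totals[1] <= totals[2] * 1.02
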