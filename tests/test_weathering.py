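"""Phosphorus stoichiometry, weathering limits and global totals."""

import numpy as np
import pytest

from cryptoweather.carbonate import SoilChemistry
from cryptoweather.grid import make_grid
from cryptoweather.weathering import (
    RockGeochem,
    Stoichiometry,
    apply_limits,
    ca_flux_to_rock_volume,
    erosion_limit,
    estimate_recycling_ratio,
    npp_weathering,
    phosphorus_demand,
    phosphorus_limited_npp,
    runoff_limit,
)


class TestPhosphorusDemand:
    def test_zero_npp_zero_demand(self):
        assert phosphorus_demand(0.0, Stoichiometry()) == 0.0

    def test_desert_worked_example(self):
        """NPP 5 g C, C:P 350, net factor 1, recycling 5 -> ~2.86e-3 g P."""
        st = Stoichiometry()
        assert st.net_loss_factor == pytest.approx(1.0)
        demand = phosphorus_demand(5.0, st)
        assert demand == pytest.approx(5.0 / 350.0 / 5.0, rel=1e-12)
        assert demand == pytest.approx(2.86e-3, rel=2e-3)

    def test_demand_inverse_in_recycling(self):
        d5 = phosphorus_demand(7.0, Stoichiometry(recycling_ratio=5.0))
        d50 = phosphorus_demand(7.0, Stoichiometry(recycling_ratio=50.0))
        assert d5 == pytest.approx(10.0 * d50)

    def test_recycling_below_one_rejected(self):
        with pytest.raises(ValueError):
            Stoichiometry(recycling_ratio=0.5)


class TestNppWeathering:
    def test_desert_rate(self):
        """Demand 2.86e-3 g P over 1432 g P/m3 rock ~ 0.002 mm yr-1."""
        w = npp_weathering(2.86e-3, RockGeochem())
        assert w * 1000.0 == pytest.approx(0.002, rel=1e-2)  # mm yr-1

    def test_inverse_proportionality_in_p_conc(self):
        w1 = npp_weathering(1.0, RockGeochem())
        w2 = npp_weathering(1.0, RockGeochem(p_conc=1432.0 / 2))
        assert w2 == pytest.approx(2 * w1)


class TestLimits:
    def test_erosion_zero_at_sea_level_and_linear(self):
        assert erosion_limit(0.0) == 0.0
        assert erosion_limit(2000.0) == pytest.approx(2 * erosion_limit(1000.0))
        assert erosion_limit(1000.0) * 1000.0 == pytest.approx(0.06, rel=1e-9)  # mm yr-1
        with pytest.raises(ValueError):
            erosion_limit(-5.0)

    def test_runoff_limit_zero_and_linear(self):
        rock = RockGeochem()
        assert runoff_limit(0.0, 1.2, rock) == 0.0
        assert runoff_limit(600.0, 1.2, rock) == pytest.approx(
            2 * runoff_limit(300.0, 1.2, rock)
        )

    def test_apply_limits_min_and_labels(self):
        w, label = apply_limits([3.6], [2.0], [5.0])
        assert w[0] == 2.0 and label[0] == "erosion"
        w, label = apply_limits([1.0], [1.0], [1.0])
        assert label[0] == "npp"  # tie priority npp > erosion > runoff
        w, label = apply_limits([2.0], [1.5], [1.5])
        assert label[0] == "erosion"

    def test_apply_limits_randomized_contract(self):
        rng = np.random.default_rng(1)
        a, b, c = rng.random((3, 40, 40))
        w, label = apply_limits(a, b, c)
        assert (w <= a).all() and (w <= b).all() and (w <= c).all()
        np.testing.assert_array_equal(w, np.minimum(a, np.minimum(b, c)))
        picked = np.select(
            [label == "npp", label == "erosion"], [a, b], default=c
        )
        np.testing.assert_allclose(picked, w)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_limits(np.ones(3), np.ones(4), np.ones(3))

    def test_constructed_limit_patterns(self):
        """Flat wet cells are erosion-limited; humid mountains are not
        runoff-limited; arid cells are runoff-limited."""
        stoich, rock = Stoichiometry(), RockGeochem()
        npp = np.array([300.0, 300.0, 300.0])        # productive everywhere
        elev = np.array([50.0, 2500.0, 2500.0])      # flat basin | mountains
        runoff = np.array([1500.0, 1500.0, 0.0])     # wet | wet | arid
        w_npp = npp_weathering(phosphorus_demand(npp, stoich), rock)
        w_ero = erosion_limit(elev)
        w_run = runoff_limit(runoff, 1.4, rock)
        _, label = apply_limits(w_npp, w_ero, w_run)
        assert label[0] == "erosion"
        assert label[1] != "runoff"
        assert label[2] == "runoff"


class TestPhosphorusFeedback:
    def test_unlimited_cell_keeps_potential(self):
        out = phosphorus_limited_npp([10.0], [2e-6], [2e-6])
        assert out[0] == 10.0

    def test_half_weathering_half_npp(self):
        out = phosphorus_limited_npp([10.0], [2e-6], [1e-6])
        assert out[0] == pytest.approx(5.0)

    def test_no_demand_no_limitation(self):
        out = phosphorus_limited_npp([0.0], [0.0], [0.0])
        assert out[0] == 0.0


class TestCaRockConversion:
    def test_calibration_anchor(self):
        assert ca_flux_to_rock_volume(7.7e12) == pytest.approx(1.8, rel=1e-9)

    def test_cross_check_pair(self):
        assert ca_flux_to_rock_volume(5.5e12) == pytest.approx(1.3, abs=0.05)

    def test_zero(self):
        assert ca_flux_to_rock_volume(0.0) == 0.0


class TestRecyclingRatio:
    def test_desert_ecosystems_imply_five_to_one(self):
        r = estimate_recycling_ratio(5.0, 0.002)
        assert round(r) == 5


class TestGlobalTotals:
    def test_uniform_field_totals_and_masking(self, paleo8, climate8, species_pool, veg_cfg):
        import dataclasses

        from cryptoweather.vegetation import run_grid
        from cryptoweather.weathering import global_totals, weathering_from_vegetation

        veg = run_grid(paleo8, climate8, veg_cfg, seed=3, species=species_pool)
        res = weathering_from_vegetation(veg, paleo8.elevation)
        s = global_totals(res, veg, paleo8.grid)
        assert s.weathering_km3_yr >= 0
        assert s.npp_gt_yr <= s.potential_npp_gt_yr + 1e-12
        assert s.npp_gt_yr <= s.gpp_gt_yr
        # masking half the vegetated cells lowers the totals
        half = veg.vegetated_mask.copy()
        idx = np.argwhere(half)
        for i, j in idx[: len(idx) // 2]:
            half[i, j] = False
        veg_half = dataclasses.replace(veg, vegetated_mask=half)
        res_half = weathering_from_vegetation(veg_half, paleo8.elevation)
        s_half = global_totals(res_half, veg_half, paleo8.grid)
        assert s_half.weathering_km3_yr < s.weathering_km3_yr

    def test_uniform_total_is_value_times_area(self):
        import dataclasses

        from cryptoweather.vegetation import VegFields
        from cryptoweather.weathering import global_totals, weathering_from_vegetation

        g = make_grid(8, 8)
        ones = np.ones(g.shape)
        veg = VegFields(
            grid=g, potential_npp=ones * 100.0, gpp=ones * 200.0, cover=ones * 0.5,
            biomass=ones * 1000.0, runoff=ones * 500.0, n_survivors=ones,
            vegetated_mask=np.ones(g.shape, dtype=bool),
            glaciated_mask=np.zeros(g.shape, dtype=bool),
        )
        res = weathering_from_vegetation(veg, np.zeros(g.shape))
        s = global_totals(res, veg, g)
        area = g.cell_area.sum()
        assert s.potential_npp_gt_yr == pytest.approx(100.0 * area / 1e15)
        assert s.gpp_gt_yr == pytest.approx(200.0 * area / 1e15)


@pytest.fixture(scope="module")
def world(paleo8, climate8, species_pool, veg_cfg):
    from cryptoweather.vegetation import run_grid

    return run_grid(paleo8, climate8, veg_cfg, seed=3, species=species_pool)


class TestDirectionalSensitivities:
    """Signs of the global responses to the main dials."""

    @staticmethod
    def _summary(veg, paleo8, **kw):
        from cryptoweather.weathering import global_totals, weathering_from_vegetation

        res = weathering_from_vegetation(veg, paleo8.elevation, **kw)
        return global_totals(res, veg, paleo8.grid)

    def test_recycling_ratio_directions(self, world, paleo8):
        s1 = self._summary(world, paleo8, stoich=Stoichiometry(recycling_ratio=1.0))
        s5 = self._summary(world, paleo8, stoich=Stoichiometry(recycling_ratio=5.0))
        s50 = self._summary(world, paleo8, stoich=Stoichiometry(recycling_ratio=50.0))
        # weathering falls with recycling; realized NPP rises with recycling
        assert s1.weathering_km3_yr >= s5.weathering_km3_yr >= s50.weathering_km3_yr
        assert s1.npp_gt_yr <= s5.npp_gt_yr <= s50.npp_gt_yr

    def test_soil_co2_direction(self, world, paleo8):
        lo = self._summary(world, paleo8, soil=SoilChemistry(soil_pco2=3000.0))
        mid = self._summary(world, paleo8, soil=SoilChemistry(soil_pco2=10000.0))
        hi = self._summary(world, paleo8, soil=SoilChemistry(soil_pco2=30000.0))
        assert lo.weathering_km3_yr <= mid.weathering_km3_yr <= hi.weathering_km3_yr

    def test_erosion_constant_direction(self, world, paleo8):
        lo = self._summary(world, paleo8, k_e=0.5 * 6e-8)
        hi = self._summary(world, paleo8, k_e=2.0 * 6e-8)
        assert lo.weathering_km3_yr <= hi.weathering_km3_yr

    def test_dampened_sensitivity_to_halved_npp(self, world, paleo8):
        """Halving potential NPP cuts realized weathering by less than half
        wherever erosion or runoff limits bind."""
        import dataclasses

        s = self._summary(world, paleo8)
        half = dataclasses.replace(world, potential_npp=world.potential_npp * 0.5)
        s_half = self._summary(half, paleo8)
        # dampened: the loss is strictly less than proportional
        assert s_half.weathering_km3_yr > 0.5 * s.weathering_km3_yr
        assert s_half.weathering_km3_yr <= s.weathering_km3_yr
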