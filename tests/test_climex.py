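"""Climatic niche engine: growth indices, soil bucket, stresses, EI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import constant_weekly
from fawrisk.climex import (
    temperature_index,
    moisture_index,
    annual_growth_index,
    annual_degree_days,
    soil_moisture_series,
    stress_index,
    apply_irrigation,
    ecoclimatic_index,
    classify_suitability,
    suitability_for_cell,
    SUITABILITY_CLASSES,
    SATURATION_CAP,
)
from fawrisk.params import SpeciesParameters


def piecewise_oracle(x, lo, opt_lo, opt_hi, hi):
    """Brute-force scalar trapezoid used as the independent reference."""
    if x <= lo or x >= hi:
        return 0.0
    if opt_lo <= x <= opt_hi:
        return 1.0
    if x < opt_lo:
        return (x - lo) / (opt_lo - lo)
    return (hi - x) / (hi - opt_hi)


class TestGrowthIndices:
    def test_temperature_index_examples(self, params):
        assert temperature_index(28.0, params) == 1.0  # inside the plateau
        assert temperature_index(9.4, params) == 0.0   # at the lower threshold
        assert temperature_index(17.7, params) == pytest.approx(0.5, abs=1e-12)
        assert temperature_index(39.5, params) == 0.0

    def test_moisture_index_examples(self, params):
        assert moisture_index(1.0, params) == 1.0
        assert moisture_index(0.1, params) == 0.0
        assert moisture_index(0.375, params) == pytest.approx(0.5, abs=1e-12)

    def test_indices_match_piecewise_oracle_densely(self, params, rng):
        xs = rng.uniform(-10, 60, size=10_000)
        expected = [piecewise_oracle(x, params.DV0, params.DV1, params.DV2,
                                     params.DV3) for x in xs]
        np.testing.assert_allclose(temperature_index(xs, params), expected,
                                   atol=1e-12)
        sms = rng.uniform(0, 3, size=10_000)
        expected = [piecewise_oracle(s, params.SM0, params.SM1, params.SM2,
                                     params.SM3) for s in sms]
        np.testing.assert_allclose(moisture_index(sms, params), expected,
                                   atol=1e-12)

    def test_annual_growth_index_sums(self):
        assert annual_growth_index(np.ones(52), np.ones(52)) == 100.0
        assert annual_growth_index(np.zeros(52), np.ones(52)) == 0.0
        half = np.r_[np.ones(26), np.zeros(26)]
        assert annual_growth_index(half, np.ones(52)) == 50.0

    def test_growth_index_rotation_invariance(self, rng):
        ti = rng.uniform(0, 1, 52)
        mi = rng.uniform(0, 1, 52)
        base = annual_growth_index(ti, mi)
        for shift in (1, 13, 37):
            assert annual_growth_index(np.roll(ti, shift), np.roll(mi, shift)) \
                == pytest.approx(base, rel=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            annual_growth_index(np.ones(52), np.ones(51))


class TestDegreeDays:
    def test_closed_forms(self, params):
        assert annual_degree_days(np.full(52, 9.4), params.DV0) == 0.0
        assert annual_degree_days(np.full(52, 26.0), params.DV0) \
            == pytest.approx(6042.4)
        # a cool cell just above the development threshold still completes
        # a generation: 400.4 degree-days exceeds PDD = 392
        dd = annual_degree_days(np.full(52, 10.5), params.DV0)
        assert dd == pytest.approx(400.4)
        assert dd >= params.PDD


class TestSoilMoisture:
    def test_dry_fixed_point(self):
        prec = np.zeros((52, 1))
        state = soil_moisture_series(prec, np.full((52, 1), 25.0),
                                     np.full((52, 1), 40.0))
        np.testing.assert_allclose(state.index, 0.0, atol=1e-9)

    def test_saturated_fixed_point(self):
        prec = np.full((52, 1), 400.0)  # far above any demand
        state = soil_moisture_series(prec, np.full((52, 1), 25.0),
                                     np.full((52, 1), 40.0))
        np.testing.assert_allclose(state.index, SATURATION_CAP, atol=1e-9)
        np.testing.assert_allclose(state.storage, 1.0, atol=1e-9)

    def test_balanced_budget_holds_initial_level(self):
        # precipitation exactly equal to demand: the bucket stays at its
        # starting level of half capacity
        tavg = np.full((52, 1), 20.0)
        rh = np.full((52, 1), 50.0)
        demand = 1.0 * 20.0 * 0.5
        state = soil_moisture_series(np.full((52, 1), demand), tavg, rh)
        np.testing.assert_allclose(state.index, 0.5, atol=1e-9)

    def test_spin_up_is_a_periodic_fixed_point(self, rng):
        prec = rng.uniform(0, 40, size=(52, 3))
        tavg = rng.uniform(-5, 35, size=(52, 3))
        rh = rng.uniform(30, 90, size=(52, 3))
        state = soil_moisture_series(prec, tavg, rh)
        # two further annual cycles change nothing beyond tolerance
        storage = state.storage[-1].copy()
        net = (prec - np.maximum(0, tavg) * (1 - rh / 100)) / 100.0
        for _ in range(2):
            for w in range(52):
                balance = storage + net[w]
                index = np.clip(balance, 0, SATURATION_CAP)
                assert np.max(np.abs(index - state.index[w])) < 1e-6
                storage = np.clip(balance, 0, 1)

    def test_wrong_week_count_raises(self):
        with pytest.raises(ValueError):
            soil_moisture_series(np.zeros((10, 1)), np.zeros((10, 1)),
                                 np.zeros((10, 1)))


class TestStressIndices:
    def test_no_breach_means_zero(self, params):
        tmin = np.full(52, 9.4)
        assert stress_index(tmin, params.TTCS, params.THCS, "below") == 0.0

    def test_permanent_cold_saturates(self, params):
        cs = stress_index(np.zeros(52), params.TTCS, params.THCS, "below")
        assert cs == 100.0

    def test_single_cold_week_accumulates_partially(self, params):
        tmin = np.full(52, 15.0)
        tmin[10] = 8.4
        cs = stress_index(tmin, params.TTCS, params.THCS, "below")
        assert 0.0 < cs < 100.0
        # one isolated breach week, deficit 1 °C, ramp factor 1
        assert cs == pytest.approx(abs(params.THCS) * 1.0 * 100.0)

    def test_ramp_accelerates_long_episodes(self, params):
        tmin = np.full(52, 15.0)
        tmin[10:20] = 5.0
        linear = stress_index(tmin, params.TTCS, params.THCS, "below", "linear")
        flat = stress_index(tmin, params.TTCS, params.THCS, "below", "flat")
        assert linear > flat

    def test_episode_wraps_across_the_year_boundary(self, params):
        # same 10-week episode, either mid-year or split across new year:
        # the wrap-aware ramp must give identical totals
        mid = np.full(52, 15.0)
        mid[20:30] = 5.0
        split = np.roll(mid, 27)
        a = stress_index(mid, params.TTCS, params.THCS, "below")
        b = stress_index(split, params.TTCS, params.THCS, "below")
        assert a == pytest.approx(b)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_warming_never_increases_cold_stress(self, seed):
        params = SpeciesParameters()
        r = np.random.default_rng(seed)
        tmin = r.uniform(-15, 20, size=52)
        warmer = tmin + r.uniform(0, 5, size=52)
        cold = stress_index(tmin, params.TTCS, params.THCS, "below")
        less_cold = stress_index(warmer, params.TTCS, params.THCS, "below")
        assert less_cold <= cold + 1e-12


class TestIrrigation:
    def test_topup_semantics(self, params):
        weekly = np.array([[1.0 * 7], [3.0 * 7]])  # 1 and 3 mm/day
        out = apply_irrigation(weekly, np.array([True]), params.irrigation_topup)
        assert out[0, 0] == pytest.approx(2.5 * 7)   # topped up to 2.5
        assert out[1, 0] == pytest.approx(3.0 * 7)   # already above, unchanged

    def test_mask_off_leaves_rain_unchanged(self, params):
        weekly = np.array([[1.0 * 7]])
        out = apply_irrigation(weekly, np.array([False]), params.irrigation_topup)
        assert out[0, 0] == pytest.approx(7.0)

    def test_additive_mode(self):
        weekly = np.array([[7.0]])
        out = apply_irrigation(weekly, np.array([True]), 2.5, mode="additive")
        assert out[0, 0] == pytest.approx(7.0 + 17.5)

    def test_irrigation_never_decreases_weekly_moisture(self, rng, params):
        prec = rng.uniform(0, 30, size=(52, 4))
        tavg = rng.uniform(10, 35, size=(52, 4))
        rh = rng.uniform(30, 70, size=(52, 4))
        wet = apply_irrigation(prec, np.ones(4, bool), params.irrigation_topup)
        dry_sm = soil_moisture_series(prec, tavg, rh)
        wet_sm = soil_moisture_series(wet, tavg, rh)
        assert np.all(wet_sm.index >= dry_sm.index - 1e-9)
        # and dry stress cannot increase
        ds_dry = stress_index(dry_sm.index, params.SMDS, params.HDS, "below")
        ds_wet = stress_index(wet_sm.index, params.SMDS, params.HDS, "below")
        assert np.all(ds_wet <= ds_dry + 1e-9)


class TestEcoclimaticIndex:
    def test_stress_free_identity(self, params):
        assert ecoclimatic_index(50.0, 0, 0, 0, 0, 1000.0, params.PDD) == 50.0

    def test_lethal_stress_forces_zero(self, params):
        assert ecoclimatic_index(80.0, 100.0, 0, 0, 0, 1000.0, params.PDD) == 0.0

    def test_multiplicative_discount(self, params):
        assert ecoclimatic_index(60.0, 50.0, 0, 0, 0, 1000.0, params.PDD) \
            == pytest.approx(30.0)

    def test_insufficient_degree_days_force_zero(self, params):
        assert ecoclimatic_index(60.0, 0, 0, 0, 0, params.PDD - 1, params.PDD) \
            == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_ei_never_exceeds_growth_index(self, seed):
        r = np.random.default_rng(seed)
        gia = r.uniform(0, 100)
        stresses = r.uniform(0, 100, size=4)
        dd = r.uniform(0, 3000)
        ei = ecoclimatic_index(gia, *stresses, dd, 392.0)
        assert 0.0 <= ei <= gia + 1e-12


class TestClassification:
    @pytest.mark.parametrize("ei,expected", [
        (0.0, "unsuitable"),
        (5.0, "marginal"),
        (15.0, "moderate"),
        (30.0, "suitable"),
        (31.0, "optimal"),
        (0.01, "marginal"),
        (100.0, "optimal"),
    ])
    def test_boundaries_are_upper_inclusive(self, ei, expected):
        assert SUITABILITY_CLASSES[classify_suitability(ei)] == expected

    def test_every_value_gets_exactly_one_class(self, rng):
        codes = classify_suitability(rng.uniform(0, 100, 1000))
        assert set(np.unique(codes)) <= {0, 1, 2, 3, 4}


class TestConstructedProfiles:
    """Whole-engine runs on designed single-cell climates."""

    def test_tropical_cell_is_optimal(self, params):
        cell = constant_weekly(tavg=27.0, prec=35.0, rh=80.0)
        res = suitability_for_cell(cell, params)
        assert res.EI > 30
        assert res.suitability == "optimal"

    def test_continental_cell_is_transient(self, params):
        cell = constant_weekly(tavg=22.0, prec=20.0, rh=70.0)
        # impose a cold winter far below the cold-stress threshold
        season = -np.cos(2 * np.pi * (np.arange(52) + 0.5) / 52)
        cell["tmin"] = 8.0 + 14.0 * season - 5.0
        cell["tmax"] = 8.0 + 14.0 * season + 5.0
        res = suitability_for_cell(cell, params)
        assert res.EI == 0.0
        assert res.GI_A > 0.0
        assert res.CS == 100.0

    def test_polar_cell_supports_no_growth(self, params):
        cell = constant_weekly(tavg=-5.0, prec=20.0, rh=80.0)
        res = suitability_for_cell(cell, params)
        assert res.GI_A == 0.0 and res.EI == 0.0
        assert res.suitability == "unsuitable"

    def test_monsoon_cell_accumulates_wet_stress(self, params):
        cell = constant_weekly(tavg=27.0, prec=30.0, rh=85.0)
        cell["prec"] = np.where(np.arange(52) % 52 < 20, 400.0, 30.0)
        res = suitability_for_cell(cell, params)
        assert res.WS > 0.0

    def test_engine_rotation_invariance_of_gi_a(self, params):
        cell = constant_weekly(tavg=22.0, prec=25.0, rh=60.0)
        season = -np.cos(2 * np.pi * (np.arange(52) + 0.5) / 52)
        for key in ("tmin", "tmax"):
            cell[key] = cell[key] + 8.0 * season
        base = suitability_for_cell(cell, params)
        rolled = {k: np.roll(v, 17) for k, v in cell.items()}
        shifted = suitability_for_cell(rolled, params)
        assert shifted.GI_A == pytest.approx(base.GI_A, rel=1e-6)
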