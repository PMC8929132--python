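import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorgenv.crop_sim import (
    CULTIVAR_PRESETS,
    REFERENCE_DENSITY,
    CultivarParams,
    SeasonIncompleteError,
    SoilLayer,
    SoilProfile,
    daily_thermal_time,
    gt_seed_set_factor,
    leaf_area_index,
    rt_index,
    saturation_vapour_pressure,
    simulate_season,
    step_water_balance,
    water_demand,
    water_supply,
)
from conftest import make_irrigated_weather


class TestThermalTime:
    @pytest.mark.parametrize(
        "tmean, expected",
        [
            (11.0, 0.0),  # base temperature
            (30.0, 19.0),  # optimum plateau point
            (36.0, 9.5),  # midpoint of the declining arm: (t_opt-t_base)/2
            (42.0, 0.0),  # upper cardinal
            (5.0, 0.0),  # below base
        ],
    )
    def test_broken_stick_response(self, cultivar, tmean, expected):
        assert daily_thermal_time(tmean, tmean, cultivar) == pytest.approx(expected)

    def test_rejects_inverted_temperatures(self, cultivar):
        with pytest.raises(ValueError):
            daily_thermal_time(25.0, 20.0, cultivar)


class TestLeafArea:
    def test_midpoint_is_half_of_maximum(self, cultivar):
        lai = leaf_area_index(cultivar.lai_midpoint, REFERENCE_DENSITY, cultivar)
        assert lai == pytest.approx(cultivar.lai_max / 2)

    def test_asymptote_is_lai_max(self, cultivar):
        lai = leaf_area_index(1e6, REFERENCE_DENSITY, cultivar)
        assert lai == pytest.approx(cultivar.lai_max)

    def test_density_scaling_is_linear(self, cultivar):
        for cum_tt in [0.0, 200.0, 500.0, 1200.0]:
            full = leaf_area_index(cum_tt, REFERENCE_DENSITY, cultivar)
            half = leaf_area_index(cum_tt, REFERENCE_DENSITY / 2, cultivar)
            assert half == pytest.approx(full / 2)

    def test_rejects_nonpositive_density(self, cultivar):
        with pytest.raises(ValueError):
            leaf_area_index(100.0, 0.0, cultivar)


class TestWaterDemand:
    def test_no_canopy_no_demand(self, cultivar):
        assert water_demand(20.0, 0.0, 34.0, 20.0, cultivar) == 0.0

    def test_zero_vpd_no_demand(self, cultivar):
        assert water_demand(20.0, 3.0, 25.0, 25.0, cultivar) == pytest.approx(0.0)

    def test_matches_hand_computed_chain(self):
        # Independent recomputation of interception -> gain -> VPD -> demand.
        cv = CultivarParams(rue=1.25, te_coeff=0.009)
        radn, lai, tmax, tmin = 20.0, 3.0, 34.0, 20.0
        interception = 1.0 - np.exp(-0.55 * lai)
        gain_kg = 1.25 * radn * interception / 1000.0
        vpd = 0.75 * (saturation_vapour_pressure(tmax) - saturation_vapour_pressure(tmin))
        assert water_demand(radn, lai, tmax, tmin, cv) == pytest.approx(
            gain_kg * vpd / 0.009, rel=1e-12
        )

    def test_rejects_negative_radiation(self, cultivar):
        with pytest.raises(ValueError):
            water_demand(-1.0, 2.0, 30.0, 20.0, cultivar)


class TestRtIndex:
    @pytest.mark.parametrize(
        "supply, demand, expected", [(5.0, 5.0, 1.0), (3.0, 0.0, 1.0), (2.0, 8.0, 0.25)]
    )
    def test_ratio_and_conventions(self, supply, demand, expected):
        assert rt_index(supply, demand) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(
        supply=st.floats(min_value=0.0, max_value=1e3),
        demand=st.floats(min_value=0.0, max_value=1e3),
    )
    def test_bounded_and_saturating(self, supply, demand):
        rt = rt_index(supply, demand)
        assert 0.0 <= rt <= 1.0
        if supply >= demand:
            assert rt == 1.0

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            rt_index(-1.0, 2.0)


def _uniform_profile(n_layers=2, thickness=200.0, kl=0.07):
    return SoilProfile(
        layers=[SoilLayer(thickness=thickness, ll=0.10, dul=0.30, kl=kl) for _ in range(n_layers)]
    )


class TestWaterSupply:
    def test_profile_at_lower_limit_supplies_nothing(self, soil):
        water = np.array([l.ll * l.thickness for l in soil.layers])
        assert water_supply(water, soil, soil.depth) == 0.0

    def test_single_layer_product(self):
        profile = _uniform_profile(n_layers=1, kl=0.07)
        layer = profile.layers[0]
        water = np.array([layer.ll * layer.thickness + 10.0])
        assert water_supply(water, profile, profile.depth) == pytest.approx(0.7)

    def test_supply_doubles_with_root_depth_on_uniform_profile(self):
        profile = _uniform_profile(n_layers=2, thickness=200.0)
        water = np.array([l.dul * l.thickness for l in profile.layers])
        one = water_supply(water, profile, 200.0)
        two = water_supply(water, profile, 400.0)
        assert two == pytest.approx(2 * one)

    def test_rejects_negative_root_depth(self, soil):
        with pytest.raises(ValueError):
            water_supply(np.zeros(len(soil.layers)), soil, -1.0)


class TestWaterBalanceStep:
    def test_identity_step(self):
        profile = _uniform_profile()
        water = profile.initial_water(0.5)
        new, fluxes = step_water_balance(water, 0.0, 0.0, 0.0, profile)
        np.testing.assert_allclose(new, water)
        assert fluxes == {"drainage": 0.0, "evaporation": 0.0, "transpiration": 0.0}

    def test_excess_rain_leaves_as_drainage(self):
        # Two-layer toy: rain beyond remaining capacity drains entirely.
        profile = _uniform_profile(n_layers=2, thickness=100.0)
        water = profile.initial_water(0.5)
        deficit = sum(
            l.dul * l.thickness - w for l, w in zip(profile.layers, water)
        )
        rain = deficit + 25.0
        new, fluxes = step_water_balance(water, rain, 0.0, 0.0, profile)
        assert fluxes["drainage"] == pytest.approx(25.0)
        np.testing.assert_allclose(
            new, [l.dul * l.thickness for l in profile.layers]
        )

    def test_mass_balance_closes_over_random_season(self, soil):
        # 120 random days: cumulative closure residual below 1e-4 mm.
        rng = np.random.default_rng(7)
        water = soil.initial_water(0.6)
        residual = 0.0
        for _ in range(120):
            rain = rng.exponential(3.0) if rng.random() < 0.3 else 0.0
            evap = rng.uniform(0.0, 2.0)
            before = water.sum()
            water, f1 = step_water_balance(water, rain, evap, 0.0, soil)
            supply = water_supply(water, soil, soil.depth)
            transp = min(rng.uniform(0.0, 6.0), supply)
            water, f2 = step_water_balance(water, 0.0, 0.0, transp, soil)
            residual += abs(
                (water.sum() - before)
                - (rain - f1["drainage"] - f1["evaporation"] - f2["transpiration"])
            )
        assert residual < 1e-4

    def test_rejects_overdraft(self):
        profile = _uniform_profile(n_layers=1)
        water = profile.initial_water(0.1)
        supply = water_supply(water, profile, profile.depth)
        with pytest.raises(ValueError):
            step_water_balance(water, 0.0, 0.0, supply * 2 + 1.0, profile)


def brute_force_gt(daily_tmax, daily_tt, cv):
    """Day-by-day loop computing the stressed fraction of the heat window."""
    cum = 0.0
    num = den = 0.0
    for tmax, tt in zip(daily_tmax, daily_tt):
        cum += tt
        if cv.tt_anthesis - cv.heat_window_before <= cum <= cv.tt_anthesis + cv.heat_window_after:
            den += tt
            if tmax > cv.heat_threshold:
                num += tt
    return 1.0 - num / den


class TestGtSeedSetFactor:
    def test_cool_window_is_stress_free(self, cultivar):
        tt = np.full(100, 15.0)
        tmax = np.full(100, 30.0)
        assert gt_seed_set_factor(tmax, tt, cultivar) == 1.0

    def test_fully_hot_window_is_fully_stressed(self, cultivar):
        tt = np.full(100, 15.0)
        tmax = np.full(100, 38.0)
        assert gt_seed_set_factor(tmax, tt, cultivar) == 0.0

    def test_half_weighted_window(self):
        # Window spans cum_tt in [75, 200]; equal daily tt of 25 puts six
        # days in the window; make three of them hot -> factor 0.5.
        cv = CultivarParams(
            tt_emerge=10.0, tt_anthesis=100.0, tt_maturity=300.0, heat_window_before=25.0
        )
        tt = np.full(12, 25.0)
        tmax = np.full(12, 30.0)
        tmax[2:5] = 35.0  # cum_tt 75, 100, 125 hot; 150, 175, 200 cool
        assert gt_seed_set_factor(tmax, tt, cv) == pytest.approx(0.5)

    def test_matches_bruteforce_on_random_seasons(self, cultivar):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = rng.integers(80, 140)
            tt = rng.uniform(5.0, 19.0, n)
            while tt.sum() < cultivar.tt_anthesis + cultivar.heat_window_after:
                tt = rng.uniform(10.0, 19.0, 140)
            tmax = rng.uniform(25.0, 40.0, len(tt))
            assert gt_seed_set_factor(tmax, tt, cultivar) == pytest.approx(
                brute_force_gt(tmax, tt, cultivar), abs=1e-12
            )

    def test_short_season_raises(self, cultivar):
        with pytest.raises(ValueError):
            gt_seed_set_factor(np.full(5, 30.0), np.full(5, 10.0), cultivar)


class TestSimulateSeason:
    def test_unstressed_control_has_rt_and_gt_of_one(self, soil, cultivar, irrigated_weather):
        res = simulate_season(
            irrigated_weather, soil, cultivar, {"sowing_date": "2001-04-05", "density": 28.0}
        )
        assert (res.daily["rt"] == 1.0).all()
        assert (res.daily["gt"] == 1.0).all()
        assert res.gt_factor == 1.0
        assert res.yield_kg_ha > 0

    def test_yield_monotone_under_rainfall_withdrawal(self, soil, cultivar):
        from sorgenv.synthetic_data import SITE_PRESETS, gen_weather

        for seed in range(20):
            weather = gen_weather(SITE_PRESETS["intermediate"], 2000, 1, seed=seed)
            try:
                full = simulate_season(
                    weather, soil, cultivar, {"sowing_date": "2000-06-01", "density": 28.0}
                )
                reduced_wx = weather.assign(rain=weather["rain"] * 0.25)
                reduced = simulate_season(
                    reduced_wx, soil, cultivar, {"sowing_date": "2000-06-01", "density": 28.0}
                )
            except SeasonIncompleteError:
                continue
            assert reduced.yield_kg_ha <= full.yield_kg_ha + 1e-9

    def test_terminal_drought_collapses_rt_and_yield(self, soil, cultivar, irrigated_weather):
        dry = irrigated_weather.assign(rain=0.0)
        res = simulate_season(
            dry,
            soil,
            cultivar,
            {"sowing_date": "2001-04-05", "density": 28.0},
            {"fraction_full_profile": 0.0},
        )
        active = res.daily.loc[res.daily["demand"] > 0, "rt"]
        assert np.all(np.diff(active) <= 1e-9)
        assert res.yield_kg_ha < 100.0

    def test_phenology_is_deterministic(self, soil, cultivar, dry_weather):
        a = simulate_season(dry_weather, soil, cultivar, {"sowing_date": "2000-06-01", "density": 28.0})
        b = simulate_season(dry_weather, soil, cultivar, {"sowing_date": "2000-06-01", "density": 28.0})
        assert a.anthesis_date == b.anthesis_date
        assert a.maturity_date == b.maturity_date
        pd.testing.assert_frame_equal(a.daily, b.daily)
        assert a.emergence_date < a.anthesis_date < a.maturity_date

    def test_indices_stay_in_unit_interval(self, soil, cultivar, dry_weather, wet_weather):
        for wx in (dry_weather, wet_weather):
            res = simulate_season(wx, soil, cultivar, {"sowing_date": "2003-06-01", "density": 28.0})
            assert res.daily["rt"].between(0, 1).all()
            assert res.daily["gt"].isin([0.0, 1.0]).all()
            assert (res.daily["cum_tt"].diff().dropna() >= 0).all()

    def test_added_heat_never_raises_seed_set(self, cultivar):
        # At fixed thermal time, warming Tmax can only grow the stressed
        # share of the window, so the GT factor is non-increasing in heat.
        rng = np.random.default_rng(3)
        for _ in range(50):
            tt = rng.uniform(8.0, 19.0, 120)
            tmax = rng.uniform(25.0, 38.0, 120)
            base = gt_seed_set_factor(tmax, tt, cultivar)
            for delta in (1.0, 3.0, 6.0):
                assert gt_seed_set_factor(tmax + delta, tt, cultivar) <= base + 1e-12

    def test_short_weather_raises_season_incomplete(self, soil, cultivar):
        weather = make_irrigated_weather(n_days=40)
        with pytest.raises(SeasonIncompleteError):
            simulate_season(weather, soil, cultivar, {"sowing_date": "2001-04-05", "density": 28.0})
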