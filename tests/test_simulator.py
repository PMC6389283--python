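"""Daily simulator: elementary process equations and whole-season invariants."""

import numpy as np
import pandas as pd
import pytest

import maizeassim as ma
from maizeassim.config import DEFAULT_CONSTANTS
from maizeassim.errors import SimulationError, ValidationError
from maizeassim.simulator import (
    GRAIN_FILL,
    JUVENILE,
    LAG,
    LEAF_GROWTH,
    SimState,
    TASSEL_INIT,
    rgfill_temperature_factor,
)


class TestElementaryEquations:
    @pytest.mark.parametrize("om,oc", [(1.0, 0.4724), (0.0, 0.0), (3.0, 1.4172)])
    def test_soil_oc_from_om(self, om, oc):
        assert ma.soil_oc_from_om(om) == pytest.approx(oc)

    def test_soil_oc_rejects_negative(self):
        with pytest.raises(ValidationError):
            ma.soil_oc_from_om(-0.1)

    @pytest.mark.parametrize("tmax,tmin,dtt", [
        (30.0, 18.0, 16.0),
        (8.0, 8.0, 0.0),
        (40.0, 36.0, 26.0),  # mean capped at 34
    ])
    def test_daily_thermal_time(self, tmax, tmin, dtt):
        assert ma.daily_thermal_time(tmax, tmin) == pytest.approx(dtt)

    @pytest.mark.parametrize("trwup,ep1,expected", [
        (6.0, 4.0, (1.0, 1.0)),       # supply/demand ratio >= 1.5
        (3.0, 4.0, (0.5, 0.75)),      # r = 0.75
        (0.0, 4.0, (0.0, 0.0)),
        (0.0, 0.0, (1.0, 1.0)),       # no demand -> unstressed
    ])
    def test_water_stress_from_supply(self, trwup, ep1, expected):
        assert ma.water_stress_from_supply(trwup, ep1) == pytest.approx(expected)

    @pytest.mark.parametrize("xn,ti,turfac,plag", [
        (1.0, 1.0, 1.0, 3.0),
        (5.0, 1.0, 0.0, 0.0),
        (5.0, 0.5, 0.8, 30.0),
    ])
    def test_leaf_area_growth(self, xn, ti, turfac, plag):
        st = SimState(istage=JUVENILE, xn=xn, ti=ti, turfac=turfac)
        assert ma.leaf_area_growth(st) == pytest.approx(plag)

    def test_leaf_weight_growth(self):
        st = SimState(istage=JUVENILE, pla=625.0)
        assert ma.leaf_weight_growth(st, 30.0) == pytest.approx(0.00116 * 30 * 5)
        assert ma.leaf_weight_growth(st, 0.0) == 0.0
        assert ma.leaf_weight_growth(st, 60.0) == pytest.approx(
            2 * ma.leaf_weight_growth(st, 30.0))

    def test_update_leaf_state_stage3_reconstruction(self):
        st = SimState(istage=LEAF_GROWTH, lfwt=0.9, pla=100.0)
        ma.update_leaf_state(st, plag=0.0, grolf=0.1, pltpop=7.41)
        assert st.pla == pytest.approx(267.0)  # (1.0)^0.8 * 267
        assert st.lai == pytest.approx((st.pla - st.senla) * 7.41 * 1e-4)

    def test_update_leaf_state_noop(self):
        st = SimState(istage=JUVENILE, pla=100.0, lfwt=0.05)
        ma.update_leaf_state(st, 0.0, 0.0, 7.41)
        assert st.pla == 100.0 and st.lfwt == 0.05
        assert st.lai == pytest.approx(100.0 * 7.41 * 1e-4)

    @pytest.mark.parametrize("swfac,plas", [
        (1.0, 0.0),
        (0.0, 50.0),   # 5% of remaining area under total stress
        (0.4, 30.0),
    ])
    def test_senescence_step(self, swfac, plas):
        st = SimState(istage=LAG, pla=1000.0, senla=0.0, swfac=swfac)
        assert ma.senescence_step(st, pltpop=7.41) == pytest.approx(plas)
        assert st.senla == pytest.approx(plas)
        assert st.senla <= st.pla

    def test_rgfill_profile(self):
        assert rgfill_temperature_factor(24.0) == 1.0
        assert rgfill_temperature_factor(16.0) == 1.0
        assert rgfill_temperature_factor(11.0) == pytest.approx(0.5)
        assert rgfill_temperature_factor(4.0) == 0.0
        assert rgfill_temperature_factor(45.0) == 0.0

    def test_grain_fill_step(self, coeffs_pc0003):
        st = SimState(istage=GRAIN_FILL, gpp=800.0, swfac=1.0)
        # RGFILL=1, GPP=800, G3=8.5 -> 6.8 g/day
        g = ma.grain_fill_step(st, tmax=28.0, tmin=20.0, coeffs=coeffs_pc0003)
        assert g == pytest.approx(800 * 8.5 * 0.001)
        st0 = SimState(istage=GRAIN_FILL, gpp=800.0, swfac=0.0)
        g0 = ma.grain_fill_step(st0, tmax=28.0, tmin=20.0, coeffs=coeffs_pc0003)
        assert g0 == pytest.approx(0.45 * g)
        cold = SimState(istage=GRAIN_FILL, gpp=800.0, swfac=1.0)
        assert ma.grain_fill_step(cold, tmax=5.0, tmin=1.0,
                                  coeffs=coeffs_pc0003) == 0.0

    @pytest.mark.parametrize("grnwt,ears,expected", [
        (1.0, 1.0, 10.0),
        (150.0, 7.41, 11115.0),
        (0.0, 7.41, 0.0),
    ])
    def test_final_yield(self, grnwt, ears, expected):
        assert ma.final_yield(grnwt, ears) == pytest.approx(expected)


class TestPhenologyAdvance:
    def test_juvenile_end_threshold(self, coeffs_pc0003):
        st = SimState(istage=JUVENILE, cumdtt=coeffs_pc0003.p1 - 10.0, xn=3.0)
        ma.advance_phenology(st, 10.0, coeffs_pc0003)
        assert st.istage == TASSEL_INIT

    def test_phyllochron_advance(self, coeffs_pc0003):
        st = SimState(istage=LEAF_GROWTH, xn=5.0)
        ma.advance_phenology(st, 49.0, coeffs_pc0003)
        assert st.ti == pytest.approx(1.0)
        assert st.xn == pytest.approx(6.0)

    def test_larger_p1_delays_tassel_initiation(self, basic_inputs):
        weather, soil, mgmt = basic_inputs
        early = ma.simulate_season(weather, soil, mgmt,
                                   ma.get_genetic_coefficients("PC0001"),
                                   water_mode="auto_irrigation")
        late = ma.simulate_season(weather, soil, mgmt,
                                  ma.get_genetic_coefficients("PC0005"),
                                  water_mode="auto_irrigation")
        def stage_start(res, stage):
            t = res.trace
            return int(t.loc[t["istage"] >= stage, "doy"].min())
        assert stage_start(late, TASSEL_INIT) > stage_start(early, TASSEL_INIT)
        assert late.maturity_doy > early.maturity_doy


class TestSeason:
    def test_trace_invariants(self, plain_bundle):
        t = plain_bundle.truth_result.trace
        grown = t[t["istage"] >= 1]
        # LAI identity after every step
        assert np.allclose(grown["lai"],
                           (grown["pla"] - grown["senla"]) * 7.41 * 1e-4)
        # senescence monotone and bounded
        assert (grown["senla"].diff().dropna() >= -1e-9).all()
        assert (grown["senla"] <= grown["pla"] + 1e-9).all()
        # grain only during effective fill, non-decreasing
        assert (t.loc[t["istage"] < GRAIN_FILL, "grnwt"] == 0).all()
        assert (t["grnwt"].diff().dropna() >= -1e-12).all()
        # stress factors in range
        assert t["turfac"].between(0, 1).all() and t["swfac"].between(0, 1).all()

    def test_auto_irrigation_never_worse(self, basic_inputs, coeffs_pc0003):
        weather, soil, mgmt = basic_inputs
        rain = ma.simulate_season(weather, soil, mgmt, coeffs_pc0003,
                                  water_mode="rain_fed")
        auto = ma.simulate_season(weather, soil, mgmt, coeffs_pc0003,
                                  water_mode="auto_irrigation")
        assert auto.yield_kg_ha >= rain.yield_kg_ha - 1e-6

    def test_forced_unstressed_independent_of_rainfall(self, coeffs_pc0003):
        soil = ma.gen_soil(7)
        mgmt = ma.Management(planting_doy=120)
        wet = ma.gen_weather(3)
        dry = ma.WeatherSeries(doy=wet.doy, srad=wet.srad, tmax=wet.tmax,
                               tmin=wet.tmin, rain=np.zeros_like(wet.rain))
        forcing = {d: ma.ForcingDay(turfac=1.0, swfac=1.0)
                   for d in range(120, 340)}
        y_wet = ma.simulate_season(wet, soil, mgmt, coeffs_pc0003,
                                   water_mode="rain_fed", forcing=forcing)
        y_dry = ma.simulate_season(dry, soil, mgmt, coeffs_pc0003,
                                   water_mode="rain_fed", forcing=forcing)
        assert y_wet.yield_kg_ha == pytest.approx(y_dry.yield_kg_ha)
        pd.testing.assert_series_equal(y_wet.trace["lai"], y_dry.trace["lai"])

    def test_forcing_all_unstressed_matches_auto_when_auto_unstressed(
            self, basic_inputs, coeffs_pc0003):
        weather, soil, mgmt = basic_inputs
        auto = ma.simulate_season(weather, soil, mgmt, coeffs_pc0003,
                                  water_mode="auto_irrigation")
        assert auto.trace["turfac"].min() == 1.0  # truly unstressed season
        forcing = {d: ma.ForcingDay(turfac=1.0, swfac=1.0)
                   for d in range(mgmt.planting_doy, 340)}
        forced = ma.simulate_season(weather, soil, mgmt, coeffs_pc0003,
                                    water_mode="rain_fed", forcing=forcing)
        assert forced.yield_kg_ha == pytest.approx(auto.yield_kg_ha)

    def test_soil_water_bounds(self, drought_bundle):
        t = drought_bundle.truth_result.trace
        assert t["avail_frac"].between(-1e-9, 1.0 + 1e-9).all()

    def test_weather_too_short(self, coeffs_pc0003):
        w = ma.gen_weather(1)
        short = ma.WeatherSeries(doy=w.doy[:200], srad=w.srad[:200],
                                 tmax=w.tmax[:200], tmin=w.tmin[:200],
                                 rain=w.rain[:200])
        with pytest.raises(SimulationError):
            ma.simulate_season(short, ma.gen_soil(2),
                               ma.Management(planting_doy=130), coeffs_pc0003)

    def test_forcing_outside_season_rejected(self, basic_inputs, coeffs_pc0003):
        weather, soil, mgmt = basic_inputs
        with pytest.raises(ValidationError):
            ma.simulate_season(weather, soil, mgmt, coeffs_pc0003,
                               forcing={50: ma.ForcingDay(turfac=0.5)})

    def test_coefficient_table_and_lookup(self):
        table = ma.load_genetic_coefficients()
        assert [g.var_id for g in table] == [f"PC000{i}" for i in range(1, 6)]
        assert table[0].p1 == 160.0 and table[0].p5 == 780.0
        assert table[0].g2 == 750.0 and table[2].p1 == 212.0
        with pytest.raises(ValidationError):
            ma.get_genetic_coefficients("PC0009")
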