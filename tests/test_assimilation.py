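"""Stress back-estimation, maturity selection, forced runs, per-grid pipeline."""

import warnings

import numpy as np
import pytest

import maizeassim as ma
from maizeassim.errors import ValidationError
from maizeassim.simulator import GRAIN_FILL, LAG


@pytest.fixture(scope="module")
def unstressed_run(plain_bundle):
    """Auto-irrigation (fully unstressed) reference season."""
    b = plain_bundle
    res = ma.simulate_season(b.weather, b.soil, b.management,
                             b.truth_result.coefficients,
                             water_mode="auto_irrigation")
    assert res.trace["turfac"].min() == 1.0
    return res


def _scaled_obs(res, factor):
    t = res.trace
    return {int(d): factor * v for d, v in zip(t["doy"], t["lai"])}


class TestStressEstimation:
    def test_ratio_one_returns_simulated_factor(self, plain_bundle, unstressed_run):
        b = plain_bundle
        obs = _scaled_obs(unstressed_run, 1.0)
        ss = ma.estimate_stress_series(obs, 125, unstressed_run.coefficients,
                                       b.weather, b.soil, b.management,
                                       water_mode="auto_irrigation")
        r = ss.records
        # the first stage-3 day carries the allometry switch of the area
        # bookkeeping (PLA jumps onto the LFWT^0.8 curve), so exclude it
        entry3 = r.loc[r["istage"] == 3, "doy"].min()
        veg = r[(r["istage"] <= 3) & (r["doy"] != entry3)]
        assert np.allclose(veg["turfac_est"], 1.0)
        assert np.allclose(veg["swfac_est"], 1.0)

    def test_ratio_half_halves_turfac(self, plain_bundle, unstressed_run):
        # observed leaf growth at half the simulated rate with TURFAC_sim = 1
        b = plain_bundle
        obs = _scaled_obs(unstressed_run, 0.5)
        ss = ma.estimate_stress_series(obs, 125, unstressed_run.coefficients,
                                       b.weather, b.soil, b.management,
                                       water_mode="auto_irrigation")
        r = ss.records
        stage12 = r[(r["istage"] <= 2) & (r["turfac_est"] > 0)]
        assert np.allclose(stage12["turfac_est"], 0.5, atol=1e-9)
        assert np.allclose(stage12["swfac_est"], 0.75, atol=1e-9)

    def test_ratio_above_one_clamped(self, plain_bundle, unstressed_run):
        b = plain_bundle
        obs = _scaled_obs(unstressed_run, 1.2)
        ss = ma.estimate_stress_series(obs, 125, unstressed_run.coefficients,
                                       b.weather, b.soil, b.management,
                                       water_mode="auto_irrigation")
        r = ss.records
        assert (r["turfac_est"] <= 1.0).all() and (r["swfac_est"] <= 1.0).all()
        stage12 = r[r["istage"] <= 2]
        assert np.allclose(stage12["turfac_est"], 1.0)

    def test_swfac_turfac_ratio_in_vegetative_stages(self, plain_bundle,
                                                     unstressed_run):
        # SWFAC_est = 1.5 * TURFAC_est whenever neither value is clamped
        b = plain_bundle
        obs = _scaled_obs(unstressed_run, 0.5)
        ss = ma.estimate_stress_series(obs, 125, unstressed_run.coefficients,
                                       b.weather, b.soil, b.management,
                                       water_mode="auto_irrigation")
        r = ss.records
        free = r[(r["istage"] <= 3) & (r["swfac_est"] < 1) & (r["turfac_est"] > 0)]
        assert len(free) > 5
        assert np.allclose(free["swfac_est"] / free["turfac_est"], 1.5)

    def test_senescence_stage_self_consistency(self, drought_bundle,
                                               truth_lai_lookup):
        # observed senescence equal to the simulated PLAS reproduces SWFAC_sim
        b = drought_bundle
        truth = b.truth_result
        ss = ma.estimate_stress_series(truth_lai_lookup, 125, truth.coefficients,
                                       b.weather, b.soil, b.management,
                                       water_mode="rain_fed")
        merged = ss.records.merge(truth.trace[["doy", "swfac"]], on="doy")
        late = merged[merged["istage"] >= LAG]
        assert len(late) > 20
        assert np.allclose(late["swfac_est"], late["swfac"], atol=1e-9)

    def test_estimates_clamped(self, drought_bundle):
        b = drought_bundle
        fit = ma.fit_reflectance_series(b.reflectance, eod=321, seed=1)
        ss = ma.estimate_stress_series(fit, 125, b.truth_result.coefficients,
                                       b.weather, b.soil, b.management,
                                       water_mode="auto_irrigation")
        r = ss.records
        assert r["turfac_est"].between(0, 1).all()
        assert r["swfac_est"].between(0, 1).all()

    def test_window_bounds(self, drought_bundle, truth_lai_lookup):
        b = drought_bundle
        base = b.truth_result
        ss = ma.estimate_stress_series(truth_lai_lookup, 125, base.coefficients,
                                       b.weather, b.soil, b.management,
                                       water_mode="rain_fed")
        lo, hi = ss.window
        assert lo == 125 + 5
        assert hi == base.maturity_doy - 5

    def test_causality(self, drought_bundle, truth_lai_lookup):
        # the day-d estimate depends only on observations up to day d
        b = drought_bundle
        coeffs = b.truth_result.coefficients
        cut = 190
        obs2 = {d: (v if d <= cut else 0.7 * v)
                for d, v in truth_lai_lookup.items()}
        kw = dict(coeffs=coeffs, weather=b.weather, soil=b.soil,
                  mgmt=b.management, water_mode="rain_fed")
        full = ma.estimate_stress_series(truth_lai_lookup, 125, **kw).records
        mod = ma.estimate_stress_series(obs2, 125, **kw).records
        a = full[full["doy"] <= cut].reset_index(drop=True)
        c = mod[mod["doy"] <= cut].reset_index(drop=True)
        assert np.allclose(a["turfac_est"], c["turfac_est"])
        assert np.allclose(a["swfac_est"], c["swfac_est"])

    def test_single_pass_approximation_close_on_unstressed(self, plain_bundle,
                                                           unstressed_run):
        b = plain_bundle
        obs = _scaled_obs(unstressed_run, 1.0)
        kw = dict(coeffs=unstressed_run.coefficients, weather=b.weather,
                  soil=b.soil, mgmt=b.management, water_mode="auto_irrigation")
        loop = ma.estimate_stress_series(obs, 125, **kw).records
        fast = ma.estimate_stress_series(obs, 125, single_pass=True, **kw).records
        assert np.allclose(loop["swfac_est"], fast["swfac_est"], atol=1e-9)


class TestClosure:
    def test_forced_factors_reproduce_truth_yield(self, drought_bundle,
                                                  truth_lai_lookup):
        b = drought_bundle
        truth = b.truth_result
        assert truth.trace["swfac"].min() < 0.5  # the drought really bites
        ss = ma.estimate_stress_series(truth_lai_lookup, 125, truth.coefficients,
                                       b.weather, b.soil, b.management,
                                       water_mode="rain_fed")
        forced = ma.run_assimilated_yield(ss, b.weather, b.soil, b.management,
                                          truth.coefficients,
                                          water_mode="rain_fed")
        assert forced.yield_kg_ha == pytest.approx(truth.yield_kg_ha, rel=0.01)


class TestMaturitySelection:
    def test_recovers_group_for_clean_scenario(self):
        # noise-free observations: the matched observation operator makes the
        # comparison exactly unbiased, so the truth group must win
        spec = ma.ScenarioSpec(planting_doy=125, maturity_group="PC0003",
                               noise_cv=0.0, missing_rate=0.0)
        b = ma.gen_scenario(21, spec)
        fit = ma.fit_reflectance_series(b.reflectance, eod=321, seed=21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            group, diffs = ma.select_maturity_group(
                fit, b.weather, b.soil, b.management,
                ma.load_genetic_coefficients(), water_mode="rain_fed",
                sample_doys=b.reflectance.doy, noise_cv=0.0)
        assert group.var_id == "PC0003"
        assert set(diffs) == {f"PC000{i}" for i in range(1, 6)}

    def test_tie_breaks_to_lowest_numbered(self, plain_bundle):
        b = plain_bundle
        fit = ma.fit_reflectance_series(b.reflectance, eod=321, seed=21)
        twin = [b.truth_result.coefficients,
                ma.GeneticCoefficients(var_id="PC0009", p1=212.0, p2=0.75,
                                       p5=850.0, g2=800.0, g3=8.5, phint=49.0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            group, diffs = ma.select_maturity_group(
                fit, b.weather, b.soil, b.management, twin,
                water_mode="rain_fed")
        # identical coefficients give identical distances; first row wins
        assert diffs["PC0003"] == diffs["PC0009"]
        assert group.var_id == "PC0003"

    def test_invalid_compare_mode(self, plain_bundle):
        b = plain_bundle
        fit = ma.fit_reflectance_series(b.reflectance, eod=321, seed=21)
        with pytest.raises(ValidationError):
            ma.select_maturity_group(fit, b.weather, b.soil, b.management,
                                     ma.load_genetic_coefficients(),
                                     compare="median")


class TestRunGrid:
    def test_schema_and_determinism(self, plain_bundle):
        b = plain_bundle
        fit = ma.fit_reflectance_series(b.reflectance, eod=321, seed=21)
        phen = ma.PhenologyParams(eod=321, tau=-95.0, rho=0.0)
        kw = dict(fit=fit, weather=b.weather, soil=b.soil, mgmt=b.management,
                  coeff_table=ma.load_genetic_coefficients(),
                  phenology_params=phen, single_pass=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = ma.run_grid("G1", **kw)
            r2 = ma.run_grid("G1", **kw)
        assert set(r1.yields) == {"default_rain", "default_auto",
                                  "stress_rain", "stress_auto"}
        assert r1.to_dict() == r2.to_dict()
        assert r1.low_confidence == fit.low_confidence
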