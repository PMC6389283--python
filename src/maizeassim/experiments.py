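"""Seeded end-to-end recovery experiments on synthetic known-truth scenarios.

These protocols exercise the full pipeline — reflectance fitting, planting
date, maturity group, stress estimation, forced yield — against truths the
generator knows, and are what the acceptance checks and the example scripts
run.  Planting-date evaluation uses phenology parameters calibrated on a
seed-disjoint batch of scenarios from the same generator, because the
published (tau, rho) pairs encode the relation between satellite phenology
and surveyed planting dates of the original study region, not of this
synthetic world (see the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assimilation import estimate_stress_series, run_assimilated_yield, select_maturity_group
from .config import Constants, DEFAULT_CONSTANTS
from .phenology import PhenologyParams, calibrate_planting_params, estimate_planting_date
from .rs_lai import LadFit, fit_reflectance_series
from .simulator import Management, load_genetic_coefficients, simulate_season
from .synthetic import DroughtSpec, ScenarioBundle, ScenarioSpec, gen_scenario

#: Latest agronomically sensible planting DOY per maturity group (longer-season
#: hybrids must be planted earlier to mature before autumn cold).
PLANTING_CAPS = {
    "PC0001": 148, "PC0002": 138, "PC0003": 130, "PC0004": 124, "PC0005": 118,
}
PLANTING_FLOOR = 112


def scenario_spec_for_seed(
    seed: int,
    drought: bool = False,
    noise_cv: float = 0.05,
    missing_rate: float = 0.1,
) -> ScenarioSpec:
    """Draw a scenario: a maturity group, a feasible planting DOY and,
    optionally, a mid-season drought."""
    rng = np.random.default_rng(seed + 500)
    gid = f"PC000{rng.integers(1, 6)}"
    planting = int(rng.integers(PLANTING_FLOOR, PLANTING_CAPS[gid] + 1))
    dspec = None
    if drought:
        start = int(rng.integers(planting + 45, planting + 70))
        dspec = DroughtSpec(start_doy=start,
                            end_doy=start + int(rng.integers(30, 50)),
                            factor=float(rng.uniform(0.05, 0.25)))
    return ScenarioSpec(planting_doy=planting, maturity_group=gid,
                        drought=dspec, noise_cv=noise_cv,
                        missing_rate=missing_rate)


def calibrate_synthetic_phenology(
    eod: int,
    n: int = 30,
    seed0: int = 1001,
    constants: Constants = DEFAULT_CONSTANTS,
) -> PhenologyParams:
    """Calibrate (tau, rho) of the planting-date model on generator scenarios
    with seeds ``seed0 .. seed0+n-1`` (keep these disjoint from evaluation
    seeds)."""
    b1s, b2s, plantings = [], [], []
    for seed in range(seed0, seed0 + n):
        spec = scenario_spec_for_seed(seed)
        bundle = gen_scenario(seed, spec, constants=constants)
        try:
            fit = fit_reflectance_series(bundle.reflectance, eod=eod,
                                         constants=constants, seed=seed)
        except Exception:  # noqa: BLE001 - drop unusable calibration samples
            continue
        b1s.append(fit.b1)
        b2s.append(fit.b2)
        plantings.append(spec.planting_doy)
    return calibrate_planting_params(b1s, b2s, plantings, eod=eod)


@dataclass
class RecoveryOutcome:
    seed: int
    true_planting: int
    est_planting: int
    true_group: str
    est_group: Optional[str]
    fit: LadFit


@dataclass
class RecoveryReport:
    outcomes: List[RecoveryOutcome]
    phenology: PhenologyParams

    @property
    def planting_errors(self) -> np.ndarray:
        return np.array([o.est_planting - o.true_planting for o in self.outcomes])

    @property
    def median_abs_planting_error(self) -> float:
        return float(np.median(np.abs(self.planting_errors)))

    @property
    def planting_rmse(self) -> float:
        e = self.planting_errors
        return float(np.sqrt(np.mean(e.astype(float) ** 2)))

    @property
    def maturity_recovery_rate(self) -> float:
        hits = [o.est_group == o.true_group for o in self.outcomes]
        return float(np.mean(hits))


def parameter_recovery_experiment(
    n: int = 20,
    seed0: int = 1,
    eod: int = 321,
    constants: Constants = DEFAULT_CONSTANTS,
    phenology: Optional[PhenologyParams] = None,
    select_water_mode: str = "rain_fed",
) -> RecoveryReport:
    """Planting-date and maturity-group recovery on ``n`` seeded scenarios.

    Maturity selection runs with the true planting date in the management
    (the selection contract requires planting to be set) under the water
    mode matching the truth runs.
    """
    if phenology is None:
        phenology = calibrate_synthetic_phenology(eod, constants=constants)
    table = load_genetic_coefficients()
    outcomes: List[RecoveryOutcome] = []
    for seed in range(seed0, seed0 + n):
        spec = scenario_spec_for_seed(seed)
        bundle = gen_scenario(seed, spec, constants=constants)
        fit = fit_reflectance_series(bundle.reflectance, eod=eod,
                                     constants=constants, seed=seed)
        est = estimate_planting_date(fit, phenology)
        est_group = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                group, _ = select_maturity_group(
                    fit, bundle.weather, bundle.soil, bundle.management,
                    table, water_mode=select_water_mode, constants=constants,
                    sample_doys=bundle.reflectance.doy,
                    noise_cv=spec.noise_cv,
                )
                est_group = group.var_id
            except Exception:  # noqa: BLE001
                pass
        outcomes.append(RecoveryOutcome(
            seed=seed, true_planting=spec.planting_doy, est_planting=est.doy,
            true_group=spec.maturity_group, est_group=est_group, fit=fit,
        ))
    return RecoveryReport(outcomes=outcomes, phenology=phenology)


@dataclass
class DroughtOutcome:
    seed: int
    truth_yield: float
    yields: Dict[str, float]  # default_rain/default_auto/stress_rain/stress_auto

    def error(self, config: str) -> float:
        return abs(self.yields[config] - self.truth_yield)


@dataclass
class DroughtReport:
    outcomes: List[DroughtOutcome]

    def median_error(self, config: str) -> float:
        return float(np.median([o.error(config) for o in self.outcomes]))

    def ordering_auto_ge_rain(self) -> bool:
        return all(o.yields["default_auto"] >= o.yields["default_rain"] - 1e-6
                   for o in self.outcomes)


def drought_assimilation_experiment(
    n: int = 20,
    seed0: int = 1,
    eod: int = 321,
    constants: Constants = DEFAULT_CONSTANTS,
    use_true_inputs: bool = True,
    phenology: Optional[PhenologyParams] = None,
) -> DroughtReport:
    """Yield-recovery comparison of the four run configurations on drought
    scenarios.

    Truth seasons are rain-fed with a mid-season drought.  With
    ``use_true_inputs`` the simulations use the true planting date and
    maturity group (isolating the value of the stress assimilation);
    otherwise planting and group are estimated from the reflectance fit.
    """
    table = load_genetic_coefficients()
    if phenology is None and not use_true_inputs:
        phenology = calibrate_synthetic_phenology(eod, constants=constants)
    outcomes: List[DroughtOutcome] = []
    for seed in range(seed0, seed0 + n):
        spec = scenario_spec_for_seed(seed, drought=True)
        bundle = gen_scenario(seed, spec, constants=constants)
        fit = fit_reflectance_series(bundle.reflectance, eod=eod,
                                     constants=constants, seed=seed)
        if use_true_inputs:
            planting = spec.planting_doy
            coeffs = bundle.truth_result.coefficients
        else:
            planting = estimate_planting_date(fit, phenology).doy
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coeffs, _ = select_maturity_group(
                    fit, bundle.weather, bundle.soil,
                    Management(planting_doy=planting), table,
                    water_mode="rain_fed", constants=constants,
                    sample_doys=bundle.reflectance.doy, noise_cv=spec.noise_cv,
                )
        mgmt = Management(planting_doy=planting)
        yields: Dict[str, float] = {}
        for mode, tag in (("rain_fed", "rain"), ("auto_irrigation", "auto")):
            default = simulate_season(bundle.weather, bundle.soil, mgmt,
                                      coeffs, water_mode=mode,
                                      constants=constants)
            yields[f"default_{tag}"] = float(default.yield_kg_ha)
            stress = estimate_stress_series(
                fit, planting, coeffs, bundle.weather, bundle.soil, mgmt,
                water_mode=mode, constants=constants,
            )
            forced = run_assimilated_yield(stress, bundle.weather, bundle.soil,
                                           mgmt, coeffs, water_mode=mode,
                                           constants=constants)
            yields[f"stress_{tag}"] = float(forced.yield_kg_ha)
        outcomes.append(DroughtOutcome(seed=seed,
                                       truth_yield=bundle.truth.yield_kg_ha,
                                       yields=yields))
    return DroughtReport(outcomes=outcomes)
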