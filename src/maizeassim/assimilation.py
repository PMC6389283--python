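"""Maturity-group selection, water-stress back-estimation, and forced runs.

The stress estimation inverts the simulator's growth equations day by day:
for each day *d* of the stress window the season is re-simulated from
planting with everything already estimated (daily LAI and both stress
factors) forced on the days before *d*; the ratio of the observed to the
simulated leaf growth increment on day *d* then rescales the simulated
stress factor.  During leaf growth (stages 1-3) the ratio is taken on LAI or
leaf-weight increments,

    TURFAC_est = (dLAI_obs / dLAI_sim) * TURFAC_sim,   SWFAC_est = 1.5 * TURFAC_est,

and during senescence (stages 4-6) on senesced leaf area,

    SWFAC_est = 1 - (-dLAI_obs,per-plant / PLAS) * (1 - SWFAC_sim),
    TURFAC_est = SWFAC_est / 1.5,

with every factor clamped to [0, 1].  Re-simulating the whole prefix each day
makes the estimate on day *d* depend only on forcing for days < d, so the
loop exactly inverts the forward model: factors extracted from a simulated
truth trajectory reproduce that trajectory's yield when forced back in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import Constants, DEFAULT_CONSTANTS
from .errors import InsufficientDataError, SimulationError, ValidationError
from .phenology import PhenologyParams, PlantingEstimate, estimate_planting_date
from .rs_lai import LadFit, lfwt_from_lai, max_lai_from_fit, fit_lad_logistic
from .simulator import (
    ForcingDay,
    GeneticCoefficients,
    Management,
    SimResult,
    SoilProfile,
    WeatherSeries,
    final_yield,
    simulate_season,
    JUVENILE, TASSEL_INIT, LEAF_GROWTH, LAG, GRAIN_FILL, MATURITY,
)

#: Increment below which the observed/simulated ratio is considered undefined.
_EPS_INCREMENT = 1e-6
#: Observed per-plant senescence (cm2 plant-1 day-1) treated as a real decline.
_EPS_OBS_SENESCENCE = 1e-3

ObservedLai = Union[LadFit, Mapping[int, float], Callable[[int], float]]


def _lai_lookup(observed: ObservedLai) -> Callable[[int], float]:
    if isinstance(observed, LadFit):
        return lambda d: float(observed.daily_lai(d))
    if callable(observed):
        return lambda d: float(observed(d))
    table = {int(k): float(v) for k, v in observed.items()}
    return lambda d: table.get(int(d), 0.0)


# ---------------------------------------------------------------------------
# stress series container
# ---------------------------------------------------------------------------

@dataclass
class StressSeries:
    """Per-day estimated stress factors and forced LAI over the stress window
    (5 days after planting to 5 days before the end of the season)."""

    records: pd.DataFrame  # doy, istage, turfac_est, swfac_est, lai_rs, lfwt_rs

    def __post_init__(self) -> None:
        needed = {"doy", "istage", "turfac_est", "swfac_est", "lai_rs"}
        missing = needed - set(self.records.columns)
        if missing:
            raise ValidationError(f"stress series missing columns {sorted(missing)}")
        for col in ("turfac_est", "swfac_est"):
            v = self.records[col]
            if ((v < 0) | (v > 1)).any():
                raise ValidationError(f"{col} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def window(self) -> Tuple[int, int]:
        return int(self.records["doy"].min()), int(self.records["doy"].max())

    def to_forcing(self, include_lai: bool = True) -> Dict[int, ForcingDay]:
        out: Dict[int, ForcingDay] = {}
        for row in self.records.itertuples(index=False):
            out[int(row.doy)] = ForcingDay(
                turfac=float(row.turfac_est),
                swfac=float(row.swfac_est),
                lai=float(row.lai_rs) if include_lai else None,
            )
        return out


# ---------------------------------------------------------------------------
# maturity group selection
# ---------------------------------------------------------------------------

def select_maturity_group(
    fit: LadFit,
    weather: WeatherSeries,
    soil: SoilProfile,
    mgmt: Management,
    coeff_table: Sequence[GeneticCoefficients],
    water_mode: str = "auto_irrigation",
    constants: Constants = DEFAULT_CONSTANTS,
    compare: str = "fitted",
    sample_doys: Optional[Sequence[int]] = None,
    noise_cv: float = 0.05,
    noise_draws: int = 5,
) -> Tuple[GeneticCoefficients, Dict[str, float]]:
    """Pick the maturity group whose simulated season best matches the fit.

    Each candidate group is simulated with the given management and water
    mode, and its season-maximum LAI is compared against the fit-derived
    maximum ``LAD(b2) - LAD(b2-1)``; the group with the smallest absolute
    difference wins (a single comparison, so RMSE reduces to |difference|),
    ties going to the lowest-numbered group.

    ``compare`` selects how the candidate's maximum is measured:
    ``"fitted"`` (default) passes each candidate trajectory through the same
    observation operator as the satellite series — post-maturity dry-down,
    composite sampling (on the observed DOYs when ``sample_doys`` is given)
    and, when ``noise_cv`` > 0, ``noise_draws`` seeded realizations of the
    nominal composite noise whose fitted maxima are averaged — so both sides
    of the comparison carry the same estimator bias.  ``"simulated"``
    compares the raw trajectory maximum instead.  Groups whose simulation
    fails are skipped with a warning.
    """
    if compare not in ("fitted", "simulated"):
        raise ValidationError(f"unknown compare mode {compare!r}")
    target = max_lai_from_fit(fit)
    diffs: Dict[str, float] = {}
    best: Optional[GeneticCoefficients] = None
    best_diff = np.inf
    for coeffs in coeff_table:
        try:
            res = simulate_season(weather, soil, mgmt, coeffs,
                                  water_mode=water_mode, constants=constants)
            if compare == "simulated":
                candidate_max = res.max_lai()
            else:
                candidate_max = _fitted_max_lai(
                    res, fit.eod, sample_doys=sample_doys,
                    noise_cv=noise_cv, noise_draws=noise_draws,
                    constants=constants,
                )
        except Exception as exc:  # noqa: BLE001 - per-group robustness
            warnings.warn(f"maturity candidate {coeffs.var_id} failed: {exc}")
            continue
        diff = abs(candidate_max - target)
        diffs[coeffs.var_id] = diff
        if diff < best_diff:  # strict < keeps the lowest-numbered on ties
            best, best_diff = coeffs, diff
    if best is None:
        raise SimulationError("all maturity-group simulations failed")
    return best, diffs


def _fitted_max_lai(
    res: SimResult,
    eod: int,
    drydown_days: int = 30,
    sample_doys: Optional[Sequence[int]] = None,
    noise_cv: float = 0.0,
    noise_draws: int = 5,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Season-maximum LAI of a simulated trajectory measured through the same
    observation operator as the satellite series: a linear post-maturity
    canopy dry-down (the sensor keeps seeing the drying leaves), 8-day
    composite sampling, LAD accumulation and the LAD-logistic fit.  With
    ``noise_cv`` > 0 the fitted maximum is averaged over ``noise_draws``
    seeded realizations of the nominal composite noise, so the candidate
    statistic carries the same noise-induced bias as the observed one."""
    from .config import COMPOSITE_INTERVAL, DOY_WINDOW
    from .rs_lai import LaiSeries, cumulative_lad, fit_reflectance_series
    from .synthetic import gen_reflectance_from_lai

    doy = res.trace["doy"].to_numpy(dtype=int)
    lai = res.trace["lai"].to_numpy(dtype=float)
    daily = dict(zip(doy.tolist(), lai.tolist()))
    last_doy, last_lai = int(doy[-1]), float(lai[-1])
    for k in range(1, drydown_days + 1):
        daily[last_doy + k] = last_lai * max(0.0, 1.0 - k / drydown_days)
    if sample_doys is None:
        lo, hi = DOY_WINDOW
        sample = np.arange(lo, hi + 1, COMPOSITE_INTERVAL)
    else:
        sample = np.asarray(sample_doys, dtype=int)
    values = np.array([daily.get(int(d), 0.0) for d in sample], dtype=float)

    if noise_cv <= 0.0:
        series = LaiSeries(doy=sample, lai=values, source="simulated")
        sdoy, lad = cumulative_lad(series)
        f = fit_lad_logistic(sdoy, lad, eod=eod, seed=0)
        return max_lai_from_fit(f)

    maxima = []
    for j in range(noise_draws):
        refl = gen_reflectance_from_lai(
            sample, values, seed=97 + j, noise_cv=noise_cv,
            missing_rate=0.0, constants=constants,
        )
        keep = np.isin(refl.doy, sample)
        sub = refl.__class__(grid_id=refl.grid_id, year=refl.year,
                             doy=refl.doy[keep], red=refl.red[keep],
                             nir=refl.nir[keep])
        f = fit_reflectance_series(sub, eod=eod, constants=constants, seed=j)
        maxima.append(max_lai_from_fit(f))
    return float(np.mean(maxima))


# ---------------------------------------------------------------------------
# day-by-day stress estimation (the re-simulation loop)
# ---------------------------------------------------------------------------

def estimate_stress_series(
    observed_lai: ObservedLai,
    planting_doy: int,
    coeffs: GeneticCoefficients,
    weather: WeatherSeries,
    soil: SoilProfile,
    mgmt: Management,
    water_mode: str = "auto_irrigation",
    constants: Constants = DEFAULT_CONSTANTS,
    single_pass: bool = False,
) -> StressSeries:
    """Back-estimate daily TURFAC/SWFAC from observed vs. simulated growth.

    ``observed_lai`` supplies the remotely sensed daily LAI (a ``LadFit``, a
    DOY-to-LAI mapping, or a callable).  The stress window runs from 5 days
    after planting (emergence) to 5 days before the unforced season's
    physiological maturity.  By default the full day-by-day re-simulation is
    performed (quadratic in season length); ``single_pass=True`` estimates
    every day from one unforced trajectory instead (faster, approximate).
    """
    if observed_lai is None:
        raise ValidationError("observed_lai is required")
    lai_at = _lai_lookup(observed_lai)
    mgmt_loc = Management(
        planting_doy=int(planting_doy), pltpop=mgmt.pltpop,
        planting_depth=mgmt.planting_depth, fertilizer=mgmt.fertilizer,
        irrigation=mgmt.irrigation,
    )

    base = simulate_season(weather, soil, mgmt_loc, coeffs,
                           water_mode=water_mode, constants=constants)
    margin = constants.stress_window_margin
    start = int(planting_doy) + margin
    end = int(base.maturity_doy) - margin
    if end <= start:
        raise InsufficientDataError("season too short for a stress window")

    pltpop = mgmt_loc.pltpop
    forcing: Dict[int, ForcingDay] = {}
    rows: List[dict] = []
    prev_turfac, prev_swfac = 1.0, 1.0
    base_trace = base.trace.set_index("doy") if single_pass else None

    for d in range(start, end + 1):
        if single_pass:
            day = base_trace.loc[d]
            prev_day = base_trace.loc[d - 1] if d - 1 in base_trace.index else None
        else:
            sim = simulate_season(weather, soil, mgmt_loc, coeffs,
                                  water_mode=water_mode, forcing=forcing,
                                  constants=constants, stop_doy=d)
            trace = sim.trace
            day = trace[trace["doy"] == d]
            if day.empty:  # forced run matured before d
                break
            day = day.iloc[0]
            prev = trace[trace["doy"] == d - 1]
            prev_day = prev.iloc[0] if not prev.empty else None

        istage = int(day["istage"])
        turfac_sim = float(day["turfac"])
        swfac_sim = float(day["swfac"])
        lai_obs_d, lai_obs_dm1 = lai_at(d), lai_at(d - 1)

        if istage in (JUVENILE, TASSEL_INIT, LEAF_GROWTH):
            if istage == LEAF_GROWTH:
                obs_inc = lfwt_from_lai(lai_obs_d, pltpop, constants) \
                    - lfwt_from_lai(lai_obs_dm1, pltpop, constants)
                sim_prev = float(prev_day["lfwt"]) if prev_day is not None else 0.0
                sim_inc = float(day["lfwt"]) - sim_prev
            else:
                obs_inc = lai_obs_d - lai_obs_dm1
                sim_prev = float(prev_day["lai"]) if prev_day is not None else 0.0
                sim_inc = float(day["lai"]) - sim_prev
            if abs(sim_inc) < _EPS_INCREMENT:
                turfac_est, swfac_est = prev_turfac, prev_swfac
            else:
                raw = (obs_inc / sim_inc) * turfac_sim
                turfac_est = float(np.clip(raw, 0.0, 1.0))
                swfac_est = float(np.clip(constants.rwuep1 * raw, 0.0, 1.0))
        else:  # senescence phase, stages 4-6
            plas = float(day["plas"])
            d_obs_pp = (lai_obs_d - lai_obs_dm1) / pltpop / 0.0001  # cm2 plant-1
            if plas < _EPS_INCREMENT:
                # senescence model: PLAS = (PLA-SENLA) * FSLFW * (1-SWFAC), so
                # as the simulated stress vanishes the update has the limit
                # SWFAC_est = 1 - (-dLAI_obs) / (FSLFW * (PLA-SENLA)); a flat
                # observation then gives 1 (which keeps the closure exact) and
                # a declining one registers the stress the simulation misses
                remaining = float(day["pla"]) - float(day["senla"])
                if remaining <= _EPS_INCREMENT:
                    raw = 1.0
                else:
                    raw = 1.0 - (-d_obs_pp) / (constants.fslfw * remaining)
            else:
                raw = 1.0 - (-d_obs_pp / plas) * (1.0 - swfac_sim)
            swfac_est = float(np.clip(raw, 0.0, 1.0))
            turfac_est = float(np.clip(raw / constants.rwuep1, 0.0, 1.0))

        lfwt_rs = float(lfwt_from_lai(lai_obs_d, pltpop, constants))
        rows.append({
            "doy": d, "istage": istage,
            "turfac_est": turfac_est, "swfac_est": swfac_est,
            "lai_rs": float(lai_obs_d), "lfwt_rs": lfwt_rs,
        })
        forcing[d] = ForcingDay(turfac=turfac_est, swfac=swfac_est,
                                lai=float(lai_obs_d))
        prev_turfac, prev_swfac = turfac_est, swfac_est

    if not rows:
        raise InsufficientDataError("no stress-window days could be estimated")
    return StressSeries(records=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# forced yield run and per-grid orchestration
# ---------------------------------------------------------------------------

def run_assimilated_yield(
    stress: StressSeries,
    weather: WeatherSeries,
    soil: SoilProfile,
    mgmt: Management,
    coeffs: GeneticCoefficients,
    water_mode: str = "auto_irrigation",
    constants: Constants = DEFAULT_CONSTANTS,
    force_lai: bool = True,
) -> SimResult:
    """Simulate the season with the estimated stress series forced in.

    TURFAC/SWFAC are replaced on every window day and, unless ``force_lai``
    is disabled, LAI is replaced by the remotely sensed value; the simulator
    free-runs outside the window.
    """
    return simulate_season(
        weather, soil, mgmt, coeffs, water_mode=water_mode,
        forcing=stress.to_forcing(include_lai=force_lai),
        constants=constants,
    )


@dataclass
class AssimilationResult:
    """One grid's full pipeline output: planting estimate, per-water-mode
    maturity group, stress series, and the four configuration yields."""

    grid_id: str
    eod: int
    planting: PlantingEstimate
    maturity_group: Dict[str, str]                 # water_mode -> var_id
    stress: Dict[str, StressSeries]                # water_mode -> series
    yields: Dict[str, Optional[float]]             # config name -> kg ha-1
    fit: LadFit
    low_confidence: bool
    errors: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "grid_id": self.grid_id,
            "eod": self.eod,
            "planting_doy": self.planting.doy,
            "planting_implausible": self.planting.implausible,
            "maturity_group": dict(self.maturity_group),
            "yields": dict(self.yields),
            "fit": self.fit.to_dict(),
            "low_confidence": self.low_confidence,
            "errors": dict(self.errors),
        }


def run_grid(
    grid_id: str,
    fit: LadFit,
    weather: WeatherSeries,
    soil: SoilProfile,
    mgmt: Management,
    coeff_table: Sequence[GeneticCoefficients],
    phenology_params: Optional[PhenologyParams] = None,
    constants: Constants = DEFAULT_CONSTANTS,
    planting_doy: Optional[int] = None,
    single_pass: bool = False,
) -> AssimilationResult:
    """Run the whole per-grid pipeline and the four run configurations.

    Configurations mirror the standard naming: ``default_rain`` and
    ``default_auto`` assimilate only planting date and maturity group under
    rain-fed / auto-irrigation water supply; ``stress_rain`` and
    ``stress_auto`` additionally force the estimated daily LAI and water
    stress factors.  ``planting_doy`` overrides the planting-date estimate
    (for known-truth experiments); per-stage failures are collected in
    ``errors`` and leave the affected yields as None.
    """
    planting = estimate_planting_date(fit, phenology_params)
    use_planting = int(planting_doy) if planting_doy is not None else planting.doy
    mgmt_loc = Management(planting_doy=use_planting, pltpop=mgmt.pltpop,
                          planting_depth=mgmt.planting_depth,
                          fertilizer=mgmt.fertilizer, irrigation=mgmt.irrigation)

    maturity: Dict[str, str] = {}
    stress: Dict[str, StressSeries] = {}
    yields: Dict[str, Optional[float]] = {
        "default_rain": None, "default_auto": None,
        "stress_rain": None, "stress_auto": None,
    }
    errors: Dict[str, str] = {}

    for mode, tag in (("rain_fed", "rain"), ("auto_irrigation", "auto")):
        try:
            coeffs, _ = select_maturity_group(
                fit, weather, soil, mgmt_loc, coeff_table,
                water_mode=mode, constants=constants,
            )
            maturity[mode] = coeffs.var_id
            default = simulate_season(weather, soil, mgmt_loc, coeffs,
                                      water_mode=mode, constants=constants)
            yields[f"default_{tag}"] = float(default.yield_kg_ha)
        except Exception as exc:  # noqa: BLE001 - collect, do not abort
            errors[f"default_{tag}"] = str(exc)
            continue
        try:
            series = estimate_stress_series(
                fit, use_planting, coeffs, weather, soil, mgmt_loc,
                water_mode=mode, constants=constants, single_pass=single_pass,
            )
            stress[mode] = series
            forced = run_assimilated_yield(series, weather, soil, mgmt_loc,
                                           coeffs, water_mode=mode,
                                           constants=constants)
            yields[f"stress_{tag}"] = float(forced.yield_kg_ha)
        except Exception as exc:  # noqa: BLE001
            errors[f"stress_{tag}"] = str(exc)

    return AssimilationResult(
        grid_id=grid_id, eod=fit.eod, planting=planting,
        maturity_group=maturity, stress=stress, yields=yields,
        fit=fit, low_confidence=fit.low_confidence, errors=errors,
    )
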