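"""Seeded known-truth generators: weather, soil, reflectance, full scenarios.

Every generator is a pure function of (seed, parameters).  The weather
generator emulates a humid-continental corn-belt climate (annual mean
temperature near 11 degC, 800-1200 mm of rain); the soil generator draws
deep silt-loam-like layered profiles; the reflectance generator inverts the
package's own LAI transfer function, adds multiplicative noise and drops
composites, emulating 8-day surface-reflectance composites over DOY 89-329.
``gen_scenario`` runs the daily simulator forward under known management to
produce a truth trajectory and yield, then encodes its LAI as reflectance —
so every downstream estimate can be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import COMPOSITE_INTERVAL, DOY_WINDOW, Constants, DEFAULT_CONSTANTS
from .errors import SimulationError, ValidationError
from .rs_lai import ReflectanceSeries
from .simulator import (
    GeneticCoefficients,
    Management,
    SimResult,
    SoilLayer,
    SoilProfile,
    WeatherSeries,
    get_genetic_coefficients,
    simulate_season,
)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClimateParams:
    """Seasonal climate shape: sinusoidal temperature cycle plus a wet-day
    rainfall process.  Defaults target an annual mean of ~11 degC and
    ~1000 mm of rain."""

    mean_temp: float = 11.0          # degC annual mean
    seasonal_amplitude: float = 14.0  # degC half-range of the annual cycle
    warmest_doy: int = 196
    diurnal_range: float = 11.0      # degC tmax - tmin
    temp_noise_sd: float = 2.5
    srad_peak: float = 22.0          # MJ m-2 d-1 midsummer clear-sky scale
    srad_winter: float = 6.0
    wet_day_prob: float = 0.45
    mean_rain_mm: float = 6.0        # per wet day
    rain_shape: float = 3.0          # gamma shape of wet-day amounts
    rain_band_mm: Tuple[float, float] = (800.0, 1200.0)


@dataclass(frozen=True)
class DroughtSpec:
    """Rainfall suppression window: wet-day rain is multiplied by ``factor``
    for start_doy <= doy <= end_doy."""

    start_doy: int
    end_doy: int
    factor: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.factor <= 1.0):
            raise ValidationError("drought factor must lie in [0, 1]")
        if self.end_doy < self.start_doy:
            raise ValidationError("drought window reversed")


def gen_weather(
    seed: int,
    year: int = 2013,
    n_days: int = 365,
    climate: ClimateParams = ClimateParams(),
    drought: Optional[DroughtSpec] = None,
) -> WeatherSeries:
    """Generate one year of daily weather (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    doy = np.arange(1, n_days + 1)
    phase = 2.0 * math.pi * (doy - climate.warmest_doy) / 365.0
    tmean = climate.mean_temp + climate.seasonal_amplitude * np.cos(phase) \
        + rng.normal(0.0, climate.temp_noise_sd, n_days)
    half = 0.5 * climate.diurnal_range
    spread = np.abs(rng.normal(half, 1.5, n_days)) + 0.25
    tmax = tmean + spread
    tmin = tmean - spread

    srad_clear = climate.srad_winter + (climate.srad_peak - climate.srad_winter) \
        * 0.5 * (1.0 + np.cos(phase))
    cloud = rng.uniform(0.55, 1.0, n_days)
    srad = np.maximum(0.5, srad_clear * cloud)

    wet = rng.random(n_days) < climate.wet_day_prob
    amounts = rng.gamma(climate.rain_shape,
                        climate.mean_rain_mm / climate.rain_shape, n_days)
    rain = np.where(wet, amounts, 0.0)
    if drought is not None:
        window = (doy >= drought.start_doy) & (doy <= drought.end_doy)
        rain = np.where(window, rain * drought.factor, rain)
        # cloudless, slightly hotter drought days
        tmax = np.where(window, tmax + 1.5, tmax)
        srad = np.where(window, np.maximum(srad, 0.9 * srad_clear), srad)

    return WeatherSeries(doy=doy, srad=srad, tmax=tmax, tmin=tmin,
                         rain=rain, year=year)


# ---------------------------------------------------------------------------
# soil
# ---------------------------------------------------------------------------

def gen_soil(seed: int, n_layers: Optional[int] = None) -> SoilProfile:
    """Draw a plausible deep corn-belt profile (4-6 layers, LL<DUL<SAT)."""
    rng = np.random.default_rng(seed)
    if n_layers is None:
        n_layers = int(rng.integers(4, 7))
    bottoms = np.cumsum(rng.uniform(15.0, 35.0, n_layers))
    layers = []
    for i, depth in enumerate(bottoms):
        ll = rng.uniform(0.10, 0.15)
        dul = ll + rng.uniform(0.10, 0.16)
        sat = dul + rng.uniform(0.06, 0.12)
        root_factor = float(np.clip(math.exp(-0.02 * (depth - bottoms[0])), 0.05, 1.0))
        layers.append(SoilLayer(depth_cm=float(depth), ll=float(ll),
                                dul=float(dul), sat=float(sat),
                                root_factor=root_factor))
    om = float(rng.uniform(1.5, 3.5))
    return SoilProfile(layers=layers, om_percent=om)


# ---------------------------------------------------------------------------
# reflectance from LAI
# ---------------------------------------------------------------------------

def lai_to_reflectance(
    lai: float, constants: Constants = DEFAULT_CONSTANTS
) -> Tuple[float, float]:
    """Invert the LAI transfer to a consistent (red, nir) pair.

    NIR follows a seasonal baseline (0.35 bare soil to 0.50 closed canopy)
    and red is solved from the target NDVI (low LAI) or simple ratio (high
    LAI); branch choice mirrors the forward transfer so the roundtrip is
    exact at zero noise.
    """
    if lai < 0:
        raise ValidationError("lai must be non-negative")
    c = constants
    nir = 0.35 + 0.15 * min(1.0, lai / 6.0)
    lai_at_threshold = (c.ndvi_branch_threshold - c.ndvi_lai_intercept) / c.ndvi_lai_slope
    if lai <= lai_at_threshold:
        ndvi = c.ndvi_lai_slope * lai + c.ndvi_lai_intercept
        red = nir * (1.0 - ndvi) / (1.0 + ndvi)
    else:
        sr = lai / c.sr_lai_slope + 1.0
        red = nir / sr
    return float(red), float(nir)


def gen_reflectance_from_lai(
    doy: Sequence[int],
    lai: Sequence[float],
    seed: int,
    noise_cv: float = 0.05,
    missing_rate: float = 0.1,
    grid_id: str = "G000",
    year: int = 2013,
    constants: Constants = DEFAULT_CONSTANTS,
) -> ReflectanceSeries:
    """Encode a daily LAI trajectory as noisy 8-day composites.

    Sampling DOYs run every ``COMPOSITE_INTERVAL`` days across the composite
    window; each band gets independent multiplicative noise with coefficient
    of variation ``noise_cv``; composites are dropped with probability
    ``missing_rate`` (at least 4 are always kept).
    """
    rng = np.random.default_rng(seed)
    daily = dict(zip((int(d) for d in doy), (float(v) for v in lai)))
    lo, hi = DOY_WINDOW
    sample_doys = np.arange(lo, hi + 1, COMPOSITE_INTERVAL)
    keep = rng.random(len(sample_doys)) >= missing_rate
    if keep.sum() < 4:
        keep[:4] = True
    out_doy, out_red, out_nir = [], [], []
    for d, k in zip(sample_doys, keep):
        if not k:
            continue
        red, nir = lai_to_reflectance(daily.get(int(d), 0.0), constants)
        if noise_cv > 0:
            red *= 1.0 + noise_cv * rng.standard_normal()
            nir *= 1.0 + noise_cv * rng.standard_normal()
        red = float(np.clip(red, 1e-3, 1.0))
        nir = float(np.clip(nir, 1e-3, 1.0))
        out_doy.append(int(d))
        out_red.append(red)
        out_nir.append(nir)
    return ReflectanceSeries(grid_id=grid_id, year=year,
                             doy=np.array(out_doy), red=np.array(out_red),
                             nir=np.array(out_nir))


# ---------------------------------------------------------------------------
# full scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Truth settings for one scenario."""

    planting_doy: int = 130
    maturity_group: str = "PC0003"
    drought: Optional[DroughtSpec] = None
    irrigation: Tuple[Tuple[int, float], ...] = ()
    noise_cv: float = 0.05
    missing_rate: float = 0.1
    drydown_days: int = 30  # post-maturity canopy decline seen by the sensor


@dataclass
class ScenarioTruth:
    seed: int
    spec: ScenarioSpec
    yield_kg_ha: float
    maturity_doy: int
    daily_doy: np.ndarray
    daily_lai: np.ndarray  # includes the post-maturity dry-down tail


@dataclass
class ScenarioBundle:
    """Everything one grid needs, plus the truth to score against."""

    grid_id: str
    weather: WeatherSeries
    soil: SoilProfile
    reflectance: ReflectanceSeries
    truth: ScenarioTruth
    truth_result: SimResult
    management: Management


def _truth_lai_with_drydown(
    result: SimResult, spec: ScenarioSpec
) -> Tuple[np.ndarray, np.ndarray]:
    """Daily LAI of the truth run extended by a linear post-maturity decline
    (leaf dry-down, which the optical sensor sees but the simulator does not
    model past physiological maturity)."""
    doy = result.trace["doy"].to_numpy()
    lai = result.trace["lai"].to_numpy().copy()
    last_doy, last_lai = int(doy[-1]), float(lai[-1])
    n = spec.drydown_days
    tail_doy = np.arange(last_doy + 1, last_doy + 1 + n)
    tail_lai = last_lai * np.maximum(0.0, 1.0 - np.arange(1, n + 1) / n)
    return (np.concatenate([doy, tail_doy]),
            np.concatenate([lai, tail_lai]))


def gen_scenario(
    seed: int,
    spec: ScenarioSpec = ScenarioSpec(),
    grid_id: Optional[str] = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> ScenarioBundle:
    """Generate a fully reproducible known-truth fixture bundle.

    The truth season is simulated rain-fed (plus any explicit irrigation
    events and drought modification of the weather); its daily LAI is
    converted to 8-day reflectance composites with noise and gaps.
    """
    grid_id = grid_id or f"G{seed:04d}"
    weather = gen_weather(seed * 7919 + 1, drought=spec.drought)
    soil = gen_soil(seed * 7919 + 2)
    coeffs = get_genetic_coefficients(spec.maturity_group)
    mgmt = Management(planting_doy=spec.planting_doy,
                      irrigation=list(spec.irrigation))
    result = simulate_season(weather, soil, mgmt, coeffs,
                             water_mode="rain_fed", constants=constants)
    doy, lai = _truth_lai_with_drydown(result, spec)
    reflectance = gen_reflectance_from_lai(
        doy, lai, seed=seed * 7919 + 3, noise_cv=spec.noise_cv,
        missing_rate=spec.missing_rate, grid_id=grid_id,
        year=weather.year, constants=constants,
    )
    truth = ScenarioTruth(
        seed=seed, spec=spec, yield_kg_ha=float(result.yield_kg_ha),
        maturity_doy=int(result.maturity_doy),
        daily_doy=doy, daily_lai=lai,
    )
    return ScenarioBundle(grid_id=grid_id, weather=weather, soil=soil,
                          reflectance=reflectance, truth=truth,
                          truth_result=result, management=mgmt)


def random_scenario_spec(
    seed: int,
    drought_prob: float = 0.5,
    noise_cv: float = 0.05,
    missing_rate: float = 0.1,
) -> ScenarioSpec:
    """Draw a scenario spec: planting DOY 120-160, random maturity group,
    and a mid-season drought with probability ``drought_prob``."""
    rng = np.random.default_rng(seed)
    planting = int(rng.integers(120, 161))
    group = f"PC000{int(rng.integers(1, 6))}"
    drought = None
    if rng.random() < drought_prob:
        start = int(rng.integers(planting + 40, planting + 70))
        drought = DroughtSpec(start_doy=start,
                              end_doy=start + int(rng.integers(25, 50)),
                              factor=float(rng.uniform(0.05, 0.3)))
    return ScenarioSpec(planting_doy=planting, maturity_group=group,
                        drought=drought, noise_cv=noise_cv,
                        missing_rate=missing_rate)
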