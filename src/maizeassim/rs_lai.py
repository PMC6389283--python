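"""Satellite reflectance to LAI, leaf-area-duration series, and the LAD-logistic fit.

The seasonal trajectory of leaf area index is summarised by a three-parameter
logistic in cumulative leaf area duration,

    LAD(t) = b3 / (1 + exp(-b1 (t - b2))),

whose derivative is the daily LAI curve.  ``b1`` is the LAI growth rate
(day^-1), ``b2`` the DOY of maximum daily LAI, and ``b3`` the cumulative LAI
at physiological maturity (m2 m-2 day).  The fit is the hub of the
assimilation: planting date, maturity group, daily LAI and leaf weight are all
derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .config import COMPOSITE_INTERVAL, DOY_WINDOW, Constants, DEFAULT_CONSTANTS
from .errors import FitError, InsufficientDataError, ValidationError

ArrayLike = Union[float, Sequence[float], np.ndarray]


# ---------------------------------------------------------------------------
# spectral indices and the LAI transfer function
# ---------------------------------------------------------------------------

def compute_ndvi(nir: ArrayLike, red: ArrayLike) -> Union[float, np.ndarray]:
    """Normalized difference vegetation index, (NIR - red) / (NIR + red)."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    s = nir + red
    if np.any(s <= 0.0):
        raise ValidationError("NDVI undefined: NIR + red must be positive")
    out = (nir - red) / s
    return float(out) if out.ndim == 0 else out


def compute_sr(nir: ArrayLike, red: ArrayLike) -> Union[float, np.ndarray]:
    """Simple ratio, NIR / red."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if np.any(red <= 0.0):
        raise ValidationError("SR undefined: red reflectance must be positive")
    out = nir / red
    return float(out) if out.ndim == 0 else out


def lai_from_reflectance(
    nir: ArrayLike,
    red: ArrayLike,
    constants: Constants = DEFAULT_CONSTANTS,
) -> Union[float, np.ndarray]:
    """Convert a red/NIR reflectance pair to green LAI (m2 m-2).

    Piecewise transfer: the NDVI branch ``(NDVI - 0.28) / 0.18`` below
    NDVI = 0.7, and the simple-ratio branch ``0.35 * (SR - 1.0)`` above it.
    Because NDVI and SR are both monotone in the NIR/red ratio the two branch
    conditions coincide (NDVI > 0.7 iff SR > 17/3), so exactly one branch
    applies and the map is invertible up to the small step at the threshold.
    Output is clamped to [0, ``lai_cap``]; NDVI below the 0.28 intercept
    (bare soil, residue) clamps to zero.
    """
    ndvi = compute_ndvi(nir, red)
    sr = compute_sr(nir, red)
    ndvi_arr = np.atleast_1d(np.asarray(ndvi, dtype=float))
    sr_arr = np.atleast_1d(np.asarray(sr, dtype=float))
    lai = np.where(
        ndvi_arr <= constants.ndvi_branch_threshold,
        (ndvi_arr - constants.ndvi_lai_intercept) / constants.ndvi_lai_slope,
        constants.sr_lai_slope * (sr_arr - 1.0),
    )
    lai = np.clip(lai, 0.0, constants.lai_cap)
    return float(lai[0]) if np.isscalar(ndvi) or np.asarray(ndvi).ndim == 0 else lai


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ReflectanceSeries:
    """Per-grid 8-day red/NIR surface-reflectance samples.

    ``doy`` must be strictly increasing within the composite window; gaps
    (missing composites) are allowed and simply widen the integration
    interval downstream.
    """

    grid_id: str
    year: int
    doy: np.ndarray
    red: np.ndarray
    nir: np.ndarray

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        self.red = np.asarray(self.red, dtype=float)
        self.nir = np.asarray(self.nir, dtype=float)
        if not (len(self.doy) == len(self.red) == len(self.nir)):
            raise ValidationError("reflectance columns have unequal lengths")
        if len(self.doy) and np.any(np.diff(self.doy) <= 0):
            raise ValidationError("doy must be strictly increasing")
        lo, hi = DOY_WINDOW
        if len(self.doy) and (self.doy.min() < lo or self.doy.max() > hi):
            raise ValidationError(f"doy outside composite window [{lo}, {hi}]")
        for name, band in (("red", self.red), ("nir", self.nir)):
            if np.any((band < 0.0) | (band > 1.0)):
                raise ValidationError(f"{name} reflectance outside [0, 1]")

    def __len__(self) -> int:
        return len(self.doy)

    def to_lai(self, constants: Constants = DEFAULT_CONSTANTS) -> "LaiSeries":
        lai = np.atleast_1d(lai_from_reflectance(self.nir, self.red, constants))
        return LaiSeries(doy=self.doy.copy(), lai=lai, source="observed")


@dataclass
class LaiSeries:
    """Daily or composite LAI samples with provenance."""

    doy: np.ndarray
    lai: np.ndarray
    source: str = "observed"  # observed | fitted | simulated

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        self.lai = np.asarray(self.lai, dtype=float)
        if len(self.doy) != len(self.lai):
            raise ValidationError("doy and lai have unequal lengths")
        if np.any(self.lai < 0.0):
            raise ValidationError("lai must be non-negative")


@dataclass
class LadFit:
    """Fitted LAD-logistic parameters plus diagnostics.

    ``low_confidence`` is set when the inflection ``b2`` lies beyond the last
    composite used (fits truncated before the peak cannot constrain it well).
    """

    b1: float
    b2: float
    b3: float
    eod: int
    rss: float
    n_points: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.b1 <= 0 or self.b3 <= 0:
            raise ValidationError("b1 and b3 must be positive")
        if self.n_points < 4:
            raise ValidationError("a LAD fit needs at least 4 points")

    # -- evaluations -------------------------------------------------------
    def lad(self, t: ArrayLike) -> Union[float, np.ndarray]:
        """Cumulative leaf area duration at DOY ``t``."""
        t = np.asarray(t, dtype=float)
        out = self.b3 / (1.0 + np.exp(-self.b1 * (t - self.b2)))
        return float(out) if out.ndim == 0 else out

    def daily_lai(self, d: ArrayLike) -> Union[float, np.ndarray]:
        """Daily LAI at DOY ``d`` (derivative of the LAD-logistic)."""
        return daily_lai_from_fit(self, d)

    def max_lai(self) -> float:
        return max_lai_from_fit(self)

    def to_dict(self) -> dict:
        return {
            "b1": self.b1, "b2": self.b2, "b3": self.b3, "eod": self.eod,
            "rss": self.rss, "n_points": self.n_points,
            "low_confidence": self.low_confidence,
        }


# ---------------------------------------------------------------------------
# LAD accumulation and fitting
# ---------------------------------------------------------------------------

def cumulative_lad(
    series: LaiSeries,
    base_interval: int = COMPOSITE_INTERVAL,
) -> Tuple[np.ndarray, np.ndarray]:
    """Accumulate LAI samples into a leaf-area-duration series.

    Rectangle rule with interval equal to the DOY difference between
    consecutive samples, so a missing composite simply widens the weight of
    the sample that follows it.  The first sample is weighted by the nominal
    composite interval.  Returns ``(doy, lad)``.
    """
    if len(series.doy) == 0:
        raise InsufficientDataError("cannot accumulate an empty LAI series")
    intervals = np.empty(len(series.doy), dtype=float)
    intervals[0] = base_interval
    intervals[1:] = np.diff(series.doy)
    lad = np.cumsum(series.lai * intervals)
    return series.doy.copy(), lad


def _logistic(t: np.ndarray, b1: float, b2: float, b3: float) -> np.ndarray:
    return b3 / (1.0 + np.exp(-b1 * (t - b2)))


def fit_lad_logistic(
    doy: ArrayLike,
    lad: ArrayLike,
    eod: int,
    seed: int = 0,
    max_restarts: int = 5,
) -> LadFit:
    """Least-squares fit of the LAD-logistic to cumulative LAD points.

    Only samples with ``doy <= eod`` enter the fit.  Starting values follow
    the shape of the data (b3 from the largest LAD, b2 from the steepest
    increase, b1 from the peak slope); up to ``max_restarts`` seeded, jittered
    restarts guard against poor local minima.
    """
    doy = np.asarray(doy, dtype=float)
    lad = np.asarray(lad, dtype=float)
    mask = doy <= eod
    t, y = doy[mask], lad[mask]
    if len(t) < 4:
        raise InsufficientDataError(
            f"LAD fit needs >= 4 points at or before EOD {eod}, got {len(t)}"
        )

    slopes = np.diff(y) / np.diff(t)
    k = int(np.argmax(slopes))
    b3_0 = 1.1 * float(np.max(y))
    b2_0 = float(0.5 * (t[k] + t[k + 1]))
    b1_0 = float(np.clip(4.0 * np.max(slopes) / b3_0, 1e-3, 1.0))

    lower = np.array([1e-4, DOY_WINDOW[0] + 1e-6, 1e-6])
    upper = np.array([2.0, 400.0, 50.0 * max(b3_0, 1.0)])

    rng = np.random.default_rng(seed)
    best = None
    x0 = np.array([b1_0, b2_0, max(b3_0, 1e-3)])
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 * rng.uniform(0.7, 1.3, size=3)
        start = np.clip(start, lower + 1e-9, upper - 1e-9)
        try:
            res = least_squares(
                lambda p: _logistic(t, *p) - y,
                start,
                bounds=(lower, upper),
                method="trf",
                max_nfev=2000,
            )
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("LAD-logistic fit did not converge after restarts")

    b1, b2, b3 = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)
    return LadFit(
        b1=b1, b2=b2, b3=b3, eod=int(eod), rss=rss, n_points=len(t),
        low_confidence=bool(b2 > eod),
    )


def fit_reflectance_series(
    series: ReflectanceSeries,
    eod: int,
    constants: Constants = DEFAULT_CONSTANTS,
    seed: int = 0,
) -> LadFit:
    """Convenience wrapper: reflectance -> LAI -> LAD -> logistic fit."""
    lai = series.to_lai(constants)
    doy, lad = cumulative_lad(lai)
    return fit_lad_logistic(doy, lad, eod=eod, seed=seed)


# ---------------------------------------------------------------------------
# quantities derived from the fit
# ---------------------------------------------------------------------------

def daily_lai_from_fit(fit: LadFit, d: ArrayLike) -> Union[float, np.ndarray]:
    """Daily LAI at DOY ``d``: the derivative of the LAD-logistic.

    LAI_RS(d) = b3 b1 exp(-b1 (d - b2)) / (1 + exp(-b1 (d - b2)))^2,
    symmetric about b2 with peak b1*b3/4.
    """
    d = np.asarray(d, dtype=float)
    e = np.exp(-fit.b1 * (d - fit.b2))
    out = fit.b3 * fit.b1 * e / (1.0 + e) ** 2
    return float(out) if out.ndim == 0 else out


def lfwt_from_lai(
    lai_rs: ArrayLike,
    pltpop: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> Union[float, np.ndarray]:
    """Per-plant leaf weight (g) from canopy LAI via the CERES allometry.

    LFWT_RS = (LAI_RS / PLTPOP / 0.0001 / 267.0)^1.25 — the exact inverse of
    the simulator's leaf-area reconstruction PLA = LFWT^0.8 * 267.0.
    """
    if pltpop <= 0:
        raise ValidationError("pltpop must be positive")
    lai_rs = np.asarray(lai_rs, dtype=float)
    if np.any(lai_rs < 0):
        raise ValidationError("lai_rs must be non-negative")
    area_pp = lai_rs / pltpop / 0.0001  # cm2 plant-1
    out = (area_pp / constants.area_per_weight) ** constants.leaf_allometry_exp
    return float(out) if out.ndim == 0 else out


def max_lai_from_fit(fit: LadFit) -> float:
    """Season-maximum daily LAI implied by the fit: LAD(b2) - LAD(b2 - 1)."""
    return float(fit.lad(fit.b2) - fit.lad(fit.b2 - 1.0))
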