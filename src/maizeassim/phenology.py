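"""Planting-date estimation from LAD-logistic parameters.

The crop phenology prediction model maps the fitted logistic parameters to
the DOY of a phenological stage:

    D = b2 + tau + rho / b1

where ``tau`` is the offset (days) between the peak-LAI date ``b2`` and the
stage, and ``rho`` expresses how a faster LAI rise (larger ``b1``) shifts the
stage earlier.  A (tau, rho) pair is calibrated per EOD; the packaged default
pairs are the published Illinois/MODIS calibration.  ``calibrate_planting_params``
refits the same linear form to any collection of (b1, b2, planting) triples,
which is required whenever the model is applied to a world (for instance, the
synthetic-truth generator of this package) whose phenology-to-b2 relation
differs from that calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import VALID_EODS
from .errors import ValidationError
from .rs_lai import LadFit

#: Planting DOY window considered plausible (mid-April to late June planting).
PLAUSIBLE_PLANTING = (90, 200)


@dataclass(frozen=True)
class PhenologyParams:
    """(tau, rho) pair of the planting-date model for one EOD."""

    eod: int
    tau: float
    rho: float

    def __post_init__(self) -> None:
        if self.eod not in VALID_EODS:
            raise ValidationError(f"eod must be one of {VALID_EODS}")


@dataclass(frozen=True)
class PlantingEstimate:
    """Estimated planting DOY with the raw model value and plausibility flag."""

    doy: int
    raw: float
    implausible: bool
    low_confidence: bool = False


def load_planting_params(eod: int) -> PhenologyParams:
    """Load the packaged (tau, rho) calibration for ``eod``."""
    if eod not in VALID_EODS:
        raise ValidationError(f"eod must be one of {VALID_EODS}, got {eod}")
    text = resources.files("maizeassim.data").joinpath(
        "phenology_planting.json"
    ).read_text()
    table = json.loads(text)["planting"]
    row = table[str(eod)]
    return PhenologyParams(eod=eod, tau=float(row["tau"]), rho=float(row["rho"]))


def estimate_planting_date(
    fit: LadFit,
    params: Optional[PhenologyParams] = None,
    plausible_window: Sequence[int] = PLAUSIBLE_PLANTING,
) -> PlantingEstimate:
    """Estimate the planting DOY from a LAD fit, D = b2 + tau + rho/b1.

    The EOD of the fit and the calibration must agree.  The result is rounded
    to the nearest integer DOY; values outside ``plausible_window`` are
    flagged, not rejected.
    """
    if params is None:
        params = load_planting_params(fit.eod)
    if params.eod != fit.eod:
        raise ValidationError(
            f"EOD mismatch: fit has {fit.eod}, parameters are for {params.eod}"
        )
    if fit.b1 <= 0:
        raise ValidationError("b1 must be positive")
    raw = fit.b2 + params.tau + params.rho / fit.b1
    doy = int(round(raw))
    lo, hi = plausible_window
    return PlantingEstimate(
        doy=doy,
        raw=float(raw),
        implausible=not (lo <= doy <= hi),
        low_confidence=fit.low_confidence,
    )


def calibrate_planting_params(
    b1: Iterable[float],
    b2: Iterable[float],
    planting_doy: Iterable[float],
    eod: int,
) -> PhenologyParams:
    """Least-squares calibration of (tau, rho) from known planting dates.

    Fits ``D - b2 = tau + rho / b1`` by ordinary least squares.  Needs at
    least two samples with distinct b1.
    """
    b1 = np.asarray(list(b1), dtype=float)
    b2 = np.asarray(list(b2), dtype=float)
    d = np.asarray(list(planting_doy), dtype=float)
    if not (len(b1) == len(b2) == len(d)):
        raise ValidationError("calibration inputs have unequal lengths")
    if len(b1) < 2:
        raise ValidationError("calibration needs at least two samples")
    if np.any(b1 <= 0):
        raise ValidationError("b1 must be positive")
    X = np.column_stack([np.ones_like(b1), 1.0 / b1])
    coef, *_ = np.linalg.lstsq(X, d - b2, rcond=None)
    return PhenologyParams(eod=eod, tau=float(coef[0]), rho=float(coef[1]))
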