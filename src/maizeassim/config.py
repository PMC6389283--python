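"""Model constants and run configuration.

All numeric constants the pipeline relies on live in one frozen dataclass so a
run can be reproduced from its resolved configuration.  Defaults are the
printed CERES-Maize values where one exists (RWUEP1, FSLFW, the allometry
coefficients, the yield factor); the remaining entries are the documented
simplified fill-ins of this package (thermal-time base/cap, bucket soil-water
parameters, phase durations).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

#: Valid last-DOY-of-data choices for the LAD-logistic fit.
VALID_EODS = (209, 257, 321)

#: First and last DOY of the 8-day composite window.
DOY_WINDOW = (89, 329)

#: Nominal spacing of composites, days.
COMPOSITE_INTERVAL = 8


@dataclass(frozen=True)
class Constants:
    """Physical and model constants with their units.

    Attributes
    ----------
    lai_cap : m2 m-2, upper clamp for remotely sensed LAI (the SR branch is
        unbounded for bright-NIR pixels).
    ndvi_branch_threshold : NDVI value separating the NDVI and SR branches of
        the reflectance-to-LAI transfer.
    rwuep1 : cell-expansion stress shaping factor; TURFAC = r / rwuep1 for
        supply/demand ratio r below rwuep1.
    fslfw : fraction of remaining leaf area senesced per day under total water
        stress.
    tbase, tmean_cap : degC, base and cap of the daily thermal-time response.
    emergence_days : days from planting to emergence.
    tassel_phyllochrons : duration of the juvenile-end to tassel-initiation
        phase, in phyllochrons.
    lag_dtt : degC day, lag between end of leaf growth and the start of
        effective grain filling.
    tlno_base, tlno_per_p1 : total leaf number = tlno_base + p1 * tlno_per_p1.
    xn_area_cap : leaf number at which per-phyllochron leaf area saturates
        (top-leaf area plateau); the XN^2 term of the expansion rate uses
        min(XN, xn_area_cap).
    uptake_rate : day-1, fraction of plant-available water a fully rooted
        layer can supply per day.
    irrigation_trigger : plant-available water fraction below which the
        automatic irrigation rule refills the profile to the drained upper
        limit.
    rgfill_temps : degC, knots (t0, t1, t2, t3) of the trapezoidal grain-fill
        temperature response (0 below t0, 1 between t1 and t2, 0 above t3).
    """

    # reflectance -> LAI
    lai_cap: float = 8.0
    ndvi_branch_threshold: float = 0.7
    ndvi_lai_slope: float = 0.18
    ndvi_lai_intercept: float = 0.28
    sr_lai_slope: float = 0.35

    # leaf area <-> weight allometry (CERES-Maize)
    area_per_weight: float = 267.0  # cm2 g^-0.8 scale factor
    leaf_allometry_exp: float = 1.25  # weight ~ area^1.25; inverse exponent 0.8

    # water stress
    rwuep1: float = 1.5
    fslfw: float = 0.05

    # thermal time and phenology
    tbase: float = 8.0
    tmean_cap: float = 34.0
    emergence_days: int = 5
    tassel_phyllochrons: float = 2.0
    lag_dtt: float = 170.0
    tlno_base: float = 12.0
    tlno_per_p1: float = 1.0 / 21.0

    # leaf growth
    plag_coeff: float = 3.0
    grolf_coeff: float = 0.00116
    xn_area_cap: float = 12.0
    init_pla: float = 1.0  # cm2 plant-1 at emergence

    # soil water / transpiration
    albedo: float = 0.23
    pt_alpha: float = 1.1  # Priestley-Taylor-style multiplier
    uptake_rate: float = 0.3
    irrigation_trigger: float = 0.5

    # grain
    rgfill_temps: Tuple[float, float, float, float] = (6.0, 16.0, 32.0, 44.0)
    swfac_grain_floor: float = 0.45  # GROGRN factor = floor + (1-floor)*SWFAC
    ears_per_plant: float = 1.0
    yield_factor: float = 10.0  # kg ha-1 per (g plant-1 * ears m-2)

    # assimilation window
    stress_window_margin: int = 5  # days trimmed at each end of the season

    def replace(self, **kwargs) -> "Constants":
        return dataclasses.replace(self, **kwargs)


DEFAULT_CONSTANTS = Constants()


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (one grid batch)."""

    eod: int = 321
    water_mode: str = "auto_irrigation"  # or "rain_fed"
    assimilation: str = "stress"  # "default" (planting+maturity) or "stress"
    seed: int = 0
    constants: Constants = dataclasses.field(default_factory=Constants)

    def __post_init__(self) -> None:
        if self.eod not in VALID_EODS:
            raise ValueError(f"eod must be one of {VALID_EODS}, got {self.eod}")
        if self.water_mode not in ("rain_fed", "auto_irrigation"):
            raise ValueError(f"unknown water_mode {self.water_mode!r}")
        if self.assimilation not in ("default", "stress"):
            raise ValueError(f"unknown assimilation level {self.assimilation!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        consts = d.pop("constants", None) or {}
        if isinstance(consts, Constants):
            constants = consts
        else:
            if "rgfill_temps" in consts:
                consts["rgfill_temps"] = tuple(consts["rgfill_temps"])
            constants = Constants(**consts)
        return cls(constants=constants, **d)
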