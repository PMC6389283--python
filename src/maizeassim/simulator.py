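"""Simplified CERES-Maize daily growth simulator.

The simulator embodies the leaf growth, senescence, water-stress and grain
equations of CERES-Maize with every non-water stress factor fixed at 1.0
(nitrogen, phosphorus, potassium, water-logging, light competition and
temperature senescence), so water supply is the only source of stress.  Around
those equations sit documented simplified components: a mean-temperature
thermal-time response, a two-phase phenology clock driven by P1/PHINT/P5, a
tipping-bucket soil water balance with a Priestley-Taylor-style transpiration
demand, and an automatic-irrigation rule that refills the profile when
plant-available water falls below a trigger fraction.

State variables keep their CERES names (PLA, SENLA, LFWT, XN, TI, GRNWT, GPP,
TRWUP, EP1, TURFAC, SWFAC) so the code reads against the crop-modelling
literature.  External forcing — daily TURFAC/SWFAC and LAI from remote
sensing — can replace the internally computed values day by day, which is the
mechanism the assimilation module builds on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import Constants, DEFAULT_CONSTANTS
from .errors import SimulationError, ValidationError

# growth stages (ISTAGE)
PRE_EMERGENCE = 0
JUVENILE = 1            # emergence to end of juvenile phase
TASSEL_INIT = 2         # end of juvenile phase to tassel initiation
LEAF_GROWTH = 3         # tassel initiation to end of leaf growth
LAG = 4                 # end of leaf growth to start of effective grain fill
GRAIN_FILL = 5          # effective grain filling
MATURITY = 6            # end of effective grain fill / physiological maturity


# ---------------------------------------------------------------------------
# input containers
# ---------------------------------------------------------------------------

@dataclass
class WeatherSeries:
    """Daily weather: DOY index, solar radiation (MJ m-2 d-1), Tmax/Tmin (degC),
    rain (mm).  Days must be consecutive."""

    doy: np.ndarray
    srad: np.ndarray
    tmax: np.ndarray
    tmin: np.ndarray
    rain: np.ndarray
    year: int = 0

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        for name in ("srad", "tmax", "tmin", "rain"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.doy)
        if not all(len(getattr(self, c)) == n for c in ("srad", "tmax", "tmin", "rain")):
            raise ValidationError("weather columns have unequal lengths")
        if n and np.any(np.diff(self.doy) != 1):
            raise ValidationError("weather days must be consecutive")
        if np.any(self.tmax < self.tmin):
            raise ValidationError("tmax must be >= tmin")
        if np.any(self.srad < 0) or np.any(self.rain < 0):
            raise ValidationError("srad and rain must be non-negative")

    def __len__(self) -> int:
        return len(self.doy)

    def index_of(self, doy: int) -> int:
        i = int(doy) - int(self.doy[0])
        if i < 0 or i >= len(self.doy):
            raise SimulationError(f"weather does not cover DOY {doy}")
        return i

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"doy": self.doy, "srad": self.srad, "tmax": self.tmax,
             "tmin": self.tmin, "rain": self.rain}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, year: int = 0) -> "WeatherSeries":
        return cls(
            doy=df["doy"].to_numpy(), srad=df["srad"].to_numpy(),
            tmax=df["tmax"].to_numpy(), tmin=df["tmin"].to_numpy(),
            rain=df["rain"].to_numpy(), year=year,
        )


@dataclass
class SoilLayer:
    """One layer: bottom depth (cm), volumetric water limits, root factor."""

    depth_cm: float
    ll: float    # lower limit of plant-extractable water
    dul: float   # drained upper limit
    sat: float   # saturation
    root_factor: float  # [0, 1] root presence weight

    def __post_init__(self) -> None:
        if not (0.0 < self.ll < self.dul < self.sat < 1.0):
            raise ValidationError("layer must satisfy 0 < LL < DUL < SAT < 1")
        if not (0.0 <= self.root_factor <= 1.0):
            raise ValidationError("root_factor must lie in [0, 1]")


def soil_oc_from_om(om_percent: float) -> float:
    """Soil organic carbon (%) from organic matter (%): OC = 0.4724 * OM."""
    if om_percent < 0:
        raise ValidationError("organic matter content must be non-negative")
    return 0.4724 * om_percent


@dataclass
class SoilProfile:
    """Layered soil profile; organic carbon derived from organic matter."""

    layers: List[SoilLayer]
    om_percent: float = 2.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError("soil profile needs at least one layer")
        depths = [l.depth_cm for l in self.layers]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValidationError("layer depths must be strictly increasing")
        if self.om_percent < 0:
            raise ValidationError("om_percent must be non-negative")

    @property
    def oc_percent(self) -> float:
        return soil_oc_from_om(self.om_percent)

    def thicknesses_cm(self) -> np.ndarray:
        depths = np.asarray([l.depth_cm for l in self.layers], dtype=float)
        return np.diff(np.concatenate([[0.0], depths]))

    def to_dict(self) -> dict:
        return {
            "om_percent": self.om_percent,
            "oc_percent": self.oc_percent,
            "layers": [
                {"depth_cm": l.depth_cm, "ll": l.ll, "dul": l.dul,
                 "sat": l.sat, "root_factor": l.root_factor}
                for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SoilProfile":
        layers = [
            SoilLayer(
                depth_cm=float(l["depth_cm"]), ll=float(l["ll"]),
                dul=float(l["dul"]), sat=float(l["sat"]),
                root_factor=float(l["root_factor"]),
            )
            for l in d["layers"]
        ]
        return cls(layers=layers, om_percent=float(d.get("om_percent", 2.0)))


@dataclass
class Management:
    """Management inputs.  Fertilizer events are carried and logged only:
    nutrient stress is disabled by assumption, so they have no physiological
    effect."""

    planting_doy: int
    pltpop: float = 7.41          # plants m-2
    planting_depth: float = 4.5   # cm
    fertilizer: List[dict] = field(default_factory=lambda: [
        {"offset_days": 0, "N": 90.0, "P": 30.0, "K": 69.0},
        {"offset_days": 14, "N": 90.0, "P": 0.0, "K": 0.0},
    ])
    irrigation: List[Tuple[int, float]] = field(default_factory=list)  # (doy, mm)

    def __post_init__(self) -> None:
        if self.pltpop <= 0:
            raise ValidationError("pltpop must be positive")
        if any(ev.get("offset_days", 0) < 0 for ev in self.fertilizer):
            raise ValidationError("fertilizer offsets must be >= 0")


@dataclass(frozen=True)
class GeneticCoefficients:
    """One maturity group's DSSAT-style coefficient row."""

    var_id: str
    p1: float     # degC day, emergence to end of juvenile phase
    p2: float     # photoperiod sensitivity (unused: constant daylength)
    p5: float     # degC day, silking to physiological maturity
    g2: float     # potential kernels per plant
    g3: float     # mg kernel-1 day-1 potential fill rate
    phint: float  # degC day per leaf tip
    name: str = ""

    def __post_init__(self) -> None:
        if min(self.p1, self.p5, self.g2, self.g3, self.phint) <= 0:
            raise ValidationError("genetic coefficients must be positive")
        if not (0.0 <= self.p2 <= 1.0):
            raise ValidationError("p2 must lie in [0, 1]")

    def total_leaf_number(self, constants: Constants = DEFAULT_CONSTANTS) -> float:
        return constants.tlno_base + self.p1 * constants.tlno_per_p1


def load_genetic_coefficients() -> List[GeneticCoefficients]:
    """The packaged maturity-group table (five generic hybrids)."""
    text = resources.files("maizeassim.data").joinpath(
        "genetic_coefficients.json"
    ).read_text()
    rows = json.loads(text)["groups"]
    return [
        GeneticCoefficients(
            var_id=r["var_id"], p1=r["p1"], p2=r["p2"], p5=r["p5"],
            g2=r["g2"], g3=r["g3"], phint=r["phint"], name=r.get("name", ""),
        )
        for r in rows
    ]


def get_genetic_coefficients(var_id: str) -> GeneticCoefficients:
    for g in load_genetic_coefficients():
        if g.var_id == var_id:
            return g
    raise ValidationError(f"unknown maturity group {var_id!r}")


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    """Daily simulator state.  Auxiliary stress factors are identically 1.0."""

    istage: int = PRE_EMERGENCE
    cumdtt: float = 0.0         # thermal time within the current early phase
    cumdtt_silk: float = 0.0    # thermal time since silking (stage 4 entry)
    xn: float = 0.0             # oldest expanding leaf number
    ti: float = 0.0             # fraction of a phyllochron completed today
    pla: float = 0.0            # cm2 plant-1
    senla: float = 0.0          # cm2 plant-1
    lfwt: float = 0.0           # g plant-1
    lai: float = 0.0            # m2 m-2
    grnwt: float = 0.0          # g plant-1
    gpp: float = 0.0            # kernels plant-1
    ears: float = 0.0           # ears m-2
    trwup: float = 0.0          # mm day-1
    ep1: float = 0.0            # mm day-1
    turfac: float = 1.0
    swfac: float = 1.0
    # auxiliary stress factors, fixed at 1.0 by assumption
    satfac: float = 1.0
    pstres2: float = 1.0
    kstres: float = 1.0
    slfc: float = 1.0
    slft: float = 1.0
    slfn: float = 1.0
    slfp: float = 1.0
    mature: bool = False


@dataclass
class ForcingDay:
    """External values replacing internal ones on one day.  ``None`` fields
    leave the internal value untouched."""

    turfac: Optional[float] = None
    swfac: Optional[float] = None
    lai: Optional[float] = None


@dataclass
class SimResult:
    """Daily trace plus season summary."""

    trace: pd.DataFrame
    yield_kg_ha: Optional[float]
    maturity_doy: Optional[int]
    harvested: bool
    coefficients: GeneticCoefficients
    water_mode: str
    planting_doy: int
    irrigation_events: List[Tuple[int, float]] = field(default_factory=list)
    fertilizer_log: List[dict] = field(default_factory=list)

    def max_lai(self) -> float:
        return float(self.trace["lai"].max())

    def day(self, doy: int) -> pd.Series:
        rows = self.trace[self.trace["doy"] == doy]
        if rows.empty:
            raise KeyError(f"DOY {doy} not in trace")
        return rows.iloc[0]


# ---------------------------------------------------------------------------
# elementary daily processes
# ---------------------------------------------------------------------------

def daily_thermal_time(
    tmax: float, tmin: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Thermal time (degC day): capped daily mean minus the 8 degC base."""
    if tmax < tmin:
        raise ValidationError("tmax must be >= tmin")
    tmean = min(0.5 * (tmax + tmin), constants.tmean_cap)
    return max(0.0, tmean - constants.tbase)


def water_stress_from_supply(
    trwup: float, ep1: float, constants: Constants = DEFAULT_CONSTANTS
) -> Tuple[float, float]:
    """(TURFAC, SWFAC) from the supply/demand ratio r = TRWUP / EP1.

    TURFAC = min(1, r / RWUEP1) and SWFAC = min(1, r), both clamped to [0, 1];
    zero or negative demand means no stress.
    """
    if ep1 <= 0.0:
        return 1.0, 1.0
    r = max(0.0, trwup) / ep1
    turfac = min(1.0, r / constants.rwuep1)
    swfac = min(1.0, r)
    return turfac, swfac


def leaf_area_growth(state: SimState, constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Potential-times-stress leaf expansion, PLAG (cm2 plant-1 day-1).

    PLAG = 3.0 * XN^2 * TI * TURFAC, with the XN^2 term saturating at
    ``xn_area_cap`` (top-leaf area plateau) and the non-water stress factors
    at their fixed value of 1.
    """
    xn_eff = min(state.xn, constants.xn_area_cap)
    aux = min(state.turfac, 1.0 - (1.0 - state.satfac),
              state.pstres2, state.kstres)
    return constants.plag_coeff * xn_eff * xn_eff * state.ti * aux


def leaf_weight_growth(
    state: SimState, plag: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Leaf weight growth, GROLF = 0.00116 * PLAG * PLA^0.25 (g plant-1 day-1)."""
    if state.pla < 0:
        raise ValidationError("pla must be non-negative")
    return constants.grolf_coeff * plag * state.pla ** 0.25


def update_leaf_state(
    state: SimState,
    plag: float,
    grolf: float,
    pltpop: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> None:
    """Apply one day of leaf growth and re-derive LAI.

    Stages 1-2 accumulate area directly (PLA += PLAG) alongside weight;
    stage 3 accumulates weight and reconstructs area through the allometry
    PLA = LFWT^0.8 * 267.0.  LAI = (PLA - SENLA) * PLTPOP * 0.0001 always.
    """
    if state.istage in (JUVENILE, TASSEL_INIT):
        state.pla += plag
        state.lfwt += grolf
    elif state.istage == LEAF_GROWTH:
        state.lfwt += grolf
        state.pla = state.lfwt ** (1.0 / constants.leaf_allometry_exp) \
            * constants.area_per_weight
    else:
        raise ValidationError("leaf growth only occurs in stages 1-3")
    state.lai = (state.pla - state.senla) * pltpop * 0.0001


def senescence_step(
    state: SimState, pltpop: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Water-driven senescence during stages 4-6; returns PLAS (cm2 plant-1 d-1).

    SLFW = (1 - FSLFW) + FSLFW * SWFAC; PLAS = (PLA - SENLA) * (1 - SLFW);
    the non-water senescence factors are fixed at 1 so SLFW is the binding
    minimum.  SENLA never exceeds PLA.
    """
    slfw = (1.0 - constants.fslfw) + constants.fslfw * state.swfac
    binding = min(slfw, state.slfc, state.slft, state.slfn, state.slfp)
    plas = (state.pla - state.senla) * (1.0 - binding)
    state.senla = min(state.pla, state.senla + plas)
    state.lai = (state.pla - state.senla) * pltpop * 0.0001
    return plas


def rgfill_temperature_factor(
    tmean: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Trapezoidal grain-fill temperature response in [0, 1]."""
    t0, t1, t2, t3 = constants.rgfill_temps
    if tmean <= t0 or tmean >= t3:
        return 0.0
    if tmean < t1:
        return (tmean - t0) / (t1 - t0)
    if tmean <= t2:
        return 1.0
    return (t3 - tmean) / (t3 - t2)


def grain_fill_step(
    state: SimState,
    tmax: float,
    tmin: float,
    coeffs: GeneticCoefficients,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """One day of grain filling; returns GROGRN (g plant-1 day-1).

    GROGRN = RGFILL * GPP * G3 * 0.001 * (0.45 + 0.55 * SWFAC); GRNWT
    accumulates.  GPP is the potential kernel number G2 (no kernel-number
    stress in this simplification).
    """
    rgfill = rgfill_temperature_factor(0.5 * (tmax + tmin), constants)
    floor = constants.swfac_grain_floor
    grogrn = rgfill * state.gpp * coeffs.g3 * 0.001 * (
        floor + (1.0 - floor) * state.swfac
    )
    state.grnwt += grogrn
    return grogrn


def final_yield(grnwt: float, ears: float, constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Grain yield (kg ha-1) = GRNWT * 10.0 * EARS."""
    return grnwt * constants.yield_factor * ears


# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------

def advance_phenology(
    state: SimState,
    dtt: float,
    coeffs: GeneticCoefficients,
    constants: Constants = DEFAULT_CONSTANTS,
) -> None:
    """Advance the stage clock by one day of thermal time.

    Stage transitions: 1->2 once thermal time since emergence reaches P1;
    2->3 after a fixed two-phyllochron tassel-initiation interval; 3->4 when
    the leaf count reaches the total leaf number; 4->5 after a fixed lag;
    5->6 (physiological maturity, terminal) once thermal time since silking
    reaches P5.  During leaf growth XN advances by dtt/PHINT and TI is the
    fraction of a phyllochron completed today.
    """
    tlno = coeffs.total_leaf_number(constants)
    if state.istage in (JUVENILE, TASSEL_INIT, LEAF_GROWTH):
        state.ti = dtt / coeffs.phint
        state.xn = min(tlno, state.xn + state.ti)
    else:
        state.ti = 0.0

    if state.istage == JUVENILE:
        state.cumdtt += dtt
        if state.cumdtt >= coeffs.p1:
            state.istage = TASSEL_INIT
            state.cumdtt = 0.0
    elif state.istage == TASSEL_INIT:
        state.cumdtt += dtt
        if state.cumdtt >= constants.tassel_phyllochrons * coeffs.phint:
            state.istage = LEAF_GROWTH
            state.cumdtt = 0.0
    elif state.istage == LEAF_GROWTH:
        if state.xn >= tlno:
            state.istage = LAG
            state.cumdtt_silk = 0.0
    if state.istage in (LAG, GRAIN_FILL, MATURITY):
        state.cumdtt_silk += dtt
        if state.istage == LAG and state.cumdtt_silk >= constants.lag_dtt:
            state.istage = GRAIN_FILL
            state.gpp = coeffs.g2
        if state.istage == GRAIN_FILL and state.cumdtt_silk >= coeffs.p5:
            state.istage = MATURITY
            state.mature = True


# ---------------------------------------------------------------------------
# soil water balance
# ---------------------------------------------------------------------------

class SoilWater:
    """Tipping-bucket soil water balance over the profile's layers.

    Water infiltrates top-down; each layer holds at most its drained upper
    limit, the excess cascading to the layer below and finally out of the
    profile.  Transpiration demand EP1 is a Priestley-Taylor-style
    radiation/temperature estimate scaled by min(1, LAI); potential root
    uptake TRWUP sums a fixed per-day fraction of each layer's plant-available
    water weighted by its root factor.  Actual extraction is min(EP1, TRWUP),
    removed proportionally to each layer's contribution.
    """

    def __init__(self, profile: SoilProfile, constants: Constants = DEFAULT_CONSTANTS):
        self.constants = constants
        thick_mm = profile.thicknesses_cm() * 10.0
        self.ll_mm = np.array([l.ll for l in profile.layers]) * thick_mm
        self.dul_mm = np.array([l.dul for l in profile.layers]) * thick_mm
        self.sat_mm = np.array([l.sat for l in profile.layers]) * thick_mm
        self.root_factor = np.array([l.root_factor for l in profile.layers])
        self.sw_mm = self.dul_mm.copy()  # start the season at field capacity

    # -- diagnostics -------------------------------------------------------
    def available_fraction(self) -> float:
        """Plant-available water as a fraction of capacity, root zone wide."""
        avail = np.maximum(0.0, self.sw_mm - self.ll_mm)
        cap = self.dul_mm - self.ll_mm
        return float(avail.sum() / cap.sum())

    def deficit_to_dul(self) -> float:
        return float(np.maximum(0.0, self.dul_mm - self.sw_mm).sum())

    # -- daily step --------------------------------------------------------
    def infiltrate(self, water_mm: float) -> float:
        """Add water top-down; returns drainage out of the profile (mm)."""
        flow = water_mm
        for i in range(len(self.sw_mm)):
            self.sw_mm[i] += flow
            flow = max(0.0, self.sw_mm[i] - self.dul_mm[i])
            self.sw_mm[i] = min(self.sw_mm[i], self.dul_mm[i])
        return flow

    def demand(self, srad: float, tmax: float, tmin: float, lai: float) -> float:
        """Potential plant transpiration EP1 (mm day-1)."""
        c = self.constants
        td = 0.6 * tmax + 0.4 * tmin
        eeq = srad * (4.88e-3 - 4.37e-3 * c.albedo) * (td + 29.0)
        eo = max(0.0, c.pt_alpha * eeq)
        return eo * min(1.0, max(0.0, lai))

    def potential_uptake(self) -> Tuple[float, np.ndarray]:
        """TRWUP (mm day-1) and the per-layer potential contributions."""
        avail = np.maximum(0.0, self.sw_mm - self.ll_mm)
        per_layer = self.constants.uptake_rate * self.root_factor * avail
        return float(per_layer.sum()), per_layer

    def extract(self, amount_mm: float, per_layer: np.ndarray) -> None:
        total = per_layer.sum()
        if total <= 0 or amount_mm <= 0:
            return
        # proportional shares; each is bounded by the layer's available water
        self.sw_mm -= per_layer * min(1.0, amount_mm / total)
        self.sw_mm = np.maximum(self.sw_mm, 0.0)


# ---------------------------------------------------------------------------
# season driver
# ---------------------------------------------------------------------------

ForcingMap = Mapping[int, ForcingDay]


def _reconcile_forced_lai(
    state: SimState, lai_forced: float, pltpop: float, constants: Constants
) -> None:
    """Rewrite leaf state so it is consistent with an externally forced LAI.

    Stages 1-3: the per-plant area implied by the forced LAI replaces PLA and
    the allometric weight replaces LFWT.  Stages 4-6: senesced area absorbs
    the difference (bounded to [0, PLA]).  The LAI identity is re-applied, so
    the stored LAI may differ from the requested value only when the bound
    binds.
    """
    lai_forced = max(0.0, lai_forced)
    area_pp = lai_forced / pltpop / 0.0001
    if state.istage in (JUVENILE, TASSEL_INIT, LEAF_GROWTH):
        state.pla = state.senla + area_pp
        state.lfwt = (max(0.0, area_pp) / constants.area_per_weight) \
            ** constants.leaf_allometry_exp
    else:
        state.senla = min(state.pla, max(0.0, state.pla - area_pp))
    state.lai = (state.pla - state.senla) * pltpop * 0.0001


def simulate_season(
    weather: WeatherSeries,
    soil: SoilProfile,
    mgmt: Management,
    coeffs: GeneticCoefficients,
    water_mode: str = "rain_fed",
    forcing: Optional[ForcingMap] = None,
    constants: Constants = DEFAULT_CONSTANTS,
    stop_doy: Optional[int] = None,
) -> SimResult:
    """Run the daily loop from planting to physiological maturity.

    Daily order: thermal time -> phenology -> soil water (with the
    auto-irrigation rule when selected) -> stress factors (replaced by
    ``forcing`` when supplied for the day) -> leaf growth or senescence ->
    grain fill -> forced-LAI reconciliation.  Raises ``SimulationError`` when
    the weather record ends before maturity (unless ``stop_doy`` is given)
    and ``ValidationError`` for forcing days outside the season.
    """
    if water_mode not in ("rain_fed", "auto_irrigation"):
        raise ValidationError(f"unknown water_mode {water_mode!r}")
    planting = int(mgmt.planting_doy)
    if planting < weather.doy[0] or planting > weather.doy[-1]:
        raise SimulationError("planting date not covered by the weather record")
    forcing = dict(forcing) if forcing else {}
    if forcing:
        last = stop_doy if stop_doy is not None else int(weather.doy[-1])
        bad = [d for d in forcing if d < planting or d > last]
        if bad:
            raise ValidationError(f"forcing days outside the season: {sorted(bad)[:5]}")

    irrigation_sched: Dict[int, float] = {}
    for doy, mm in mgmt.irrigation:
        irrigation_sched[int(doy)] = irrigation_sched.get(int(doy), 0.0) + float(mm)

    state = SimState()
    bucket = SoilWater(soil, constants)
    emergence = planting + constants.emergence_days
    rows: List[dict] = []
    irrigation_events: List[Tuple[int, float]] = []
    fertilizer_log = [
        {"doy": planting + int(ev.get("offset_days", 0)), **ev}
        for ev in mgmt.fertilizer
    ]
    maturity_doy: Optional[int] = None
    prev_lai = 0.0

    i0 = weather.index_of(planting)
    for i in range(i0, len(weather)):
        doy = int(weather.doy[i])
        srad, tmax, tmin, rain = (
            float(weather.srad[i]), float(weather.tmax[i]),
            float(weather.tmin[i]), float(weather.rain[i]),
        )
        dtt = daily_thermal_time(tmax, tmin, constants)

        if doy == emergence:
            state.istage = JUVENILE
            state.xn = 1.0
            state.pla = constants.init_pla
            state.lfwt = (constants.init_pla / constants.area_per_weight) \
                ** constants.leaf_allometry_exp
            state.lai = state.pla * mgmt.pltpop * 0.0001
            state.ears = mgmt.pltpop * constants.ears_per_plant

        if state.istage != PRE_EMERGENCE:
            advance_phenology(state, dtt, coeffs, constants)

        # water balance (runs every day, also pre-emergence)
        water_in = rain + irrigation_sched.get(doy, 0.0)
        if water_mode == "auto_irrigation" and state.istage != PRE_EMERGENCE:
            if bucket.available_fraction() < constants.irrigation_trigger:
                applied = bucket.deficit_to_dul()
                water_in += applied
                irrigation_events.append((doy, applied))
        drainage = bucket.infiltrate(water_in)
        state.ep1 = bucket.demand(srad, tmax, tmin, prev_lai)
        state.trwup, per_layer = bucket.potential_uptake()
        bucket.extract(min(state.ep1, state.trwup), per_layer)

        state.turfac, state.swfac = water_stress_from_supply(
            state.trwup, state.ep1, constants
        )
        fday = forcing.get(doy)
        if fday is not None:
            if fday.turfac is not None:
                state.turfac = min(1.0, max(0.0, fday.turfac))
            if fday.swfac is not None:
                state.swfac = min(1.0, max(0.0, fday.swfac))

        plag = grolf = plas = grogrn = 0.0
        if state.istage in (JUVENILE, TASSEL_INIT, LEAF_GROWTH):
            plag = leaf_area_growth(state, constants)
            grolf = leaf_weight_growth(state, plag, constants)
            update_leaf_state(state, plag, grolf, mgmt.pltpop, constants)
        elif state.istage in (LAG, GRAIN_FILL, MATURITY):
            plas = senescence_step(state, mgmt.pltpop, constants)
            if state.istage == GRAIN_FILL:
                grogrn = grain_fill_step(state, tmax, tmin, coeffs, constants)

        if fday is not None and fday.lai is not None and state.istage != PRE_EMERGENCE:
            _reconcile_forced_lai(state, fday.lai, mgmt.pltpop, constants)

        rows.append({
            "doy": doy, "istage": state.istage, "dtt": dtt,
            "lai": state.lai, "pla": state.pla, "senla": state.senla,
            "lfwt": state.lfwt, "xn": state.xn, "ti": state.ti,
            "turfac": state.turfac, "swfac": state.swfac,
            "trwup": state.trwup, "ep1": state.ep1,
            "plag": plag, "grolf": grolf, "plas": plas,
            "grogrn": grogrn, "grnwt": state.grnwt,
            "rain": rain, "drainage": drainage,
            "irrigation": water_in - rain,
            "avail_frac": bucket.available_fraction(),
        })
        prev_lai = state.lai

        if state.mature:
            maturity_doy = doy
            break
        if stop_doy is not None and doy >= stop_doy:
            break

    if maturity_doy is None and stop_doy is None:
        raise SimulationError(
            "weather record ended before the crop reached maturity"
        )

    harvested = maturity_doy is not None
    yld = final_yield(state.grnwt, state.ears, constants) if harvested else None
    return SimResult(
        trace=pd.DataFrame(rows),
        yield_kg_ha=yld,
        maturity_doy=maturity_doy,
        harvested=harvested,
        coefficients=coeffs,
        water_mode=water_mode,
        planting_doy=planting,
        irrigation_events=irrigation_events,
        fertilizer_log=fertilizer_log,
    )
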