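"""CSV/JSON readers and writers for the pipeline's interchange formats.

Schemas
-------
reflectance CSV : grid_id, year, doy, red, nir (fractions; ``scale`` converts
    raw composite integers, e.g. 1e-4)
weather CSV     : doy, srad, tmax, tmin, rain (one row per day)
soil JSON       : {"om_percent": float, "layers": [{depth_cm, ll, dul, sat,
    root_factor}, ...]}
fit JSON        : list of {grid_id, year, eod, b1, b2, b3, rss, n_points,
    low_confidence}
stress CSV      : grid_id, doy, istage, turfac_est, swfac_est, lai_rs
trace CSV       : the daily simulator trace as produced by ``simulate_season``

Validation failures report the offending rows.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rs_lai import LadFit, ReflectanceSeries
from .simulator import SimResult, SoilProfile, WeatherSeries

PathLike = Union[str, Path]


# -- reflectance -----------------------------------------------------------

def read_reflectance_csv(
    path: PathLike, scale: float = 1.0
) -> List[ReflectanceSeries]:
    """Read per-grid reflectance series; returns one series per (grid, year)."""
    df = pd.read_csv(path)
    required = {"grid_id", "year", "doy", "red", "nir"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"reflectance CSV missing columns {sorted(missing)}")
    df = df.copy()
    df[["red", "nir"]] = df[["red", "nir"]] * scale
    bad = df[(df["red"] < 0) | (df["red"] > 1) | (df["nir"] < 0) | (df["nir"] > 1)]
    if not bad.empty:
        raise ValidationError(
            f"reflectance outside [0, 1] at rows {bad.index.tolist()[:5]}"
        )
    out = []
    for (grid_id, year), g in df.groupby(["grid_id", "year"], sort=True):
        g = g.sort_values("doy")
        out.append(ReflectanceSeries(
            grid_id=str(grid_id), year=int(year),
            doy=g["doy"].to_numpy(), red=g["red"].to_numpy(),
            nir=g["nir"].to_numpy(),
        ))
    return out


def write_reflectance_csv(path: PathLike, series: Iterable[ReflectanceSeries]) -> None:
    frames = [
        pd.DataFrame({"grid_id": s.grid_id, "year": s.year, "doy": s.doy,
                      "red": s.red, "nir": s.nir})
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# -- weather / soil --------------------------------------------------------

def read_weather_csv(path: PathLike, year: int = 0) -> WeatherSeries:
    df = pd.read_csv(path)
    required = {"doy", "srad", "tmax", "tmin", "rain"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"weather CSV missing columns {sorted(missing)}")
    return WeatherSeries.from_dataframe(df.sort_values("doy"), year=year)


def write_weather_csv(path: PathLike, weather: WeatherSeries) -> None:
    weather.to_dataframe().to_csv(path, index=False)


def read_soil_json(path: PathLike) -> SoilProfile:
    with open(path) as fh:
        return SoilProfile.from_dict(json.load(fh))


def write_soil_json(path: PathLike, soil: SoilProfile) -> None:
    with open(path, "w") as fh:
        json.dump(soil.to_dict(), fh, indent=1)


# -- fits ------------------------------------------------------------------

def write_fits_json(
    path: PathLike, fits: Dict[str, LadFit], year: Optional[int] = None
) -> None:
    records = []
    for grid_id, fit in fits.items():
        rec = {"grid_id": grid_id, **fit.to_dict()}
        if year is not None:
            rec["year"] = year
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def read_fits_json(path: PathLike) -> Dict[str, LadFit]:
    with open(path) as fh:
        records = json.load(fh)
    out = {}
    for rec in records:
        out[rec["grid_id"]] = LadFit(
            b1=rec["b1"], b2=rec["b2"], b3=rec["b3"], eod=int(rec["eod"]),
            rss=rec.get("rss", float("nan")), n_points=int(rec["n_points"]),
            low_confidence=bool(rec.get("low_confidence", False)),
        )
    return out


# -- stress series / traces ------------------------------------------------

def write_stress_csv(path: PathLike, stress_by_grid: Dict[str, "pd.DataFrame"]) -> None:
    frames = []
    for grid_id, df in stress_by_grid.items():
        f = df.copy()
        f.insert(0, "grid_id", grid_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_trace_csv(path: PathLike, result: SimResult) -> None:
    result.trace.to_csv(path, index=False)


def write_json(path: PathLike, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
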