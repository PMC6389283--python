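"""Yield aggregation and agreement statistics (R2, RMSE, NRMSE).

NRMSE (RMSE as a percentage of the mean observation) is classified with the
conventional bands: excellent below 10%, good to 20%, fair to 30%, poor
above; band boundaries fall to the better class.  R2 is the squared Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

NRMSE_BANDS = ((10.0, "excellent"), (20.0, "good"), (30.0, "fair"))


def _pair(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValidationError("predicted and observed differ in length")
    if p.size == 0:
        raise ValidationError("empty comparison")
    return p, o


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean squared error between paired vectors."""
    p, o = _pair(predicted, observed)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def classify_nrmse(nrmse_percent: float) -> str:
    for bound, klass in NRMSE_BANDS:
        if nrmse_percent <= bound:
            return klass
    return "poor"


def nrmse(rmse_value: float, observed: Sequence[float]) -> tuple[float, str]:
    """Normalized RMSE (%) = RMSE * 100 / mean(observed), with its class."""
    o = np.asarray(observed, dtype=float)
    if o.size == 0:
        raise ValidationError("empty observation vector")
    m = float(np.mean(o))
    if m <= 0:
        raise ValidationError("mean observed must be positive for NRMSE")
    value = float(rmse_value) * 100.0 / m
    return value, classify_nrmse(value)


def r_squared(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Squared Pearson correlation between predictions and observations."""
    p, o = _pair(predicted, observed)
    if p.size < 2:
        raise ValidationError("R2 needs at least two comparisons")
    if np.std(p) == 0 or np.std(o) == 0:
        raise ValidationError("R2 undefined for zero-variance input")
    r = stats.pearsonr(p, o).statistic
    return float(r * r)


@dataclass(frozen=True)
class EvalStats:
    """Agreement summary for one (configuration, EOD) comparison."""

    r2: float
    rmse: float
    nrmse: float  # percent
    n: int
    klass: str

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "nrmse": self.nrmse,
                "n": self.n, "class": self.klass}


def evaluate(predicted: Sequence[float], observed: Sequence[float]) -> EvalStats:
    """All three statistics for one paired comparison."""
    p, o = _pair(predicted, observed)
    e = rmse(p, o)
    nr, klass = nrmse(e, o)
    return EvalStats(r2=r_squared(p, o), rmse=e, nrmse=nr, n=int(p.size),
                     klass=klass)


def aggregate_yields(
    yields: pd.DataFrame,
    region_map: Mapping[str, str],
    value_col: str = "yield_kg_ha",
    grid_col: str = "grid_id",
    weights: Optional[Mapping[str, float]] = None,
) -> pd.Series:
    """Aggregate grid yields to region means.

    Every grid must appear in ``region_map``; the aggregate is the unweighted
    mean unless per-grid ``weights`` (for example areas) are supplied.
    Returns a Series indexed by region.
    """
    df = yields.copy()
    missing = sorted(set(df[grid_col]) - set(region_map))
    if missing:
        raise ValidationError(f"grids without a region: {missing[:5]}")
    df["region"] = df[grid_col].map(region_map)
    if weights is None:
        return df.groupby("region")[value_col].mean()
    df["_w"] = df[grid_col].map(dict(weights)).astype(float)
    if df["_w"].isna().any() or (df["_w"] <= 0).any():
        raise ValidationError("weights must be positive and cover all grids")
    grouped = df.groupby("region").apply(
        lambda g: np.average(g[value_col], weights=g["_w"]),
        include_groups=False,
    )
    grouped.name = value_col
    return grouped
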