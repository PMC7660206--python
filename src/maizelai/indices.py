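"""Vegetation indices and per-date empirical LAI regression.

Implements the five indices used for maize canopies with five-band UAV
reflectance (blue 490, green 550, red 680, red edge 720, NIR 800 nm):
NDVI, RVI, OSAVI, EVI2 and MTVI2.  A linear model LAI = a·VI + b is fitted
per observation date, the index with the highest |R| is selected, and
Pearson-correlation significance is classified with a two-sided t test
("**" for p < 0.01, "*" for p < 0.05, "ns" otherwise).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InputError, UndefinedValueError

__all__ = [
    "BAND_NAMES",
    "INDEX_ORDER",
    "BandReflectance",
    "LinearVIModel",
    "compute_vi",
    "vi_table",
    "fit_linear_model",
    "select_best_vi",
    "significance_class",
    "estimate_lai_map",
]

logger = logging.getLogger(__name__)

BAND_NAMES = ("blue", "green", "red", "rededge", "nir")
INDEX_ORDER = ("NDVI", "RVI", "OSAVI", "EVI2", "MTVI2")


@dataclass(frozen=True)
class BandReflectance:
    """Surface reflectance of one pixel or quadrat, each band in [0, 1]."""

    blue: float
    green: float
    red: float
    rededge: float
    nir: float

    def __post_init__(self) -> None:
        for name in BAND_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InputError(f"band {name}={v} outside [0, 1]")


def _ndvi(nir, red, green):
    den = nir + red
    return np.where(den != 0, (nir - red) / np.where(den != 0, den, 1.0), np.nan)


def _rvi(nir, red, green):
    return np.where(red != 0, nir / np.where(red != 0, red, 1.0), np.nan)


def _osavi(nir, red, green):
    return 1.16 * (nir - red) / (nir + red + 0.16)


def _evi2(nir, red, green):
    return 2.5 * (nir - red) / (nir + 2.4 * red + 1.0)


def _mtvi2(nir, red, green):
    num = 1.5 * (1.2 * (nir - green) - 2.5 * (red - green))
    disc = (2.0 * nir + 1.0) ** 2 - (6.0 * nir - 5.0 * np.sqrt(red)) - 0.5
    return np.where(disc > 0, num / np.sqrt(np.where(disc > 0, disc, 1.0)), np.nan)


_FORMULAS = {"NDVI": _ndvi, "RVI": _rvi, "OSAVI": _osavi, "EVI2": _evi2, "MTVI2": _mtvi2}


def compute_vi(bands: BandReflectance, index_name: str) -> float:
    """Evaluate one vegetation index for a single reflectance sample.

    Raises :class:`UndefinedValueError` where the index is mathematically
    undefined (zero denominator; non-positive MTVI2 discriminant).
    """
    if index_name not in _FORMULAS:
        raise InputError(f"unknown index {index_name!r}; choose from {INDEX_ORDER}")
    value = _FORMULAS[index_name](bands.nir, bands.red, bands.green)
    value = float(value)
    if not math.isfinite(value):
        raise UndefinedValueError(f"{index_name} undefined for bands {bands}")
    return value


def vi_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorised indices for a reflectance table with band columns.

    Undefined values become NaN.  Non-band columns (quadrat_id, doy, ...)
    are carried through.
    """
    missing = [b for b in ("green", "red", "nir") if b not in frame.columns]
    if missing:
        raise InputError(f"reflectance table lacks columns {missing}")
    nir = frame["nir"].to_numpy(float)
    red = frame["red"].to_numpy(float)
    green = frame["green"].to_numpy(float)
    out = frame.drop(columns=[c for c in BAND_NAMES if c in frame.columns]).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, fn in _FORMULAS.items():
            out[name] = fn(nir, red, green)
    return out


@dataclass(frozen=True)
class LinearVIModel:
    """Per-date empirical model LAI = a·VI + b with its fit diagnostics."""

    index_name: str
    slope: float
    intercept: float
    r: float
    n: int
    significance: str

    def predict(self, vi):
        return self.slope * np.asarray(vi, dtype=float) + self.intercept


def significance_class(r: float, n: int) -> str:
    """Two-sided t-test class for a Pearson correlation.

    "**" for p < 0.01, "*" for p < 0.05, "ns" otherwise; |r| = 1 is "**"
    by convention (p → 0).
    """
    if n < 3:
        raise InputError("need n >= 3 for a significance test")
    if abs(r) >= 1.0:
        return "**"
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def fit_linear_model(vi, lai_obs, index_name: str = "VI") -> LinearVIModel:
    """Ordinary least squares of observed LAI on a vegetation index."""
    vi = np.asarray(vi, dtype=float)
    lai_obs = np.asarray(lai_obs, dtype=float)
    if vi.shape != lai_obs.shape:
        raise InputError("vi and lai_obs must have equal length")
    if vi.size < 3:
        raise InputError("need at least 3 samples")
    if np.ptp(vi) == 0:
        raise DegenerateFitError("vegetation index is constant; no line can be fitted")
    res = stats.linregress(vi, lai_obs)
    r = float(res.rvalue)
    return LinearVIModel(
        index_name=index_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        n=int(vi.size),
        significance=significance_class(r, int(vi.size)),
    )


def select_best_vi(models: Mapping[str, "LinearVIModel | float"] | Iterable[LinearVIModel]) -> str:
    """Name of the index whose model has the largest |r|.

    Ties are broken by the canonical listing order NDVI, RVI, OSAVI, EVI2,
    MTVI2.  Accepts a mapping name -> model (or name -> r) or an iterable
    of fitted models.
    """
    if isinstance(models, Mapping):
        items = list(models.items())
    else:
        items = [(m.index_name, m) for m in models]
    if not items:
        raise InputError("no models to select from")

    def abs_r(value) -> float:
        return abs(value.r) if isinstance(value, LinearVIModel) else abs(float(value))

    def order(name: str) -> int:
        return INDEX_ORDER.index(name) if name in INDEX_ORDER else len(INDEX_ORDER)

    best_name, _ = min(items, key=lambda kv: (-abs_r(kv[1]), order(kv[0])))
    return best_name


def estimate_lai_map(reflectance: pd.DataFrame, model: LinearVIModel) -> pd.Series:
    """Apply a fitted empirical model to a reflectance table.

    Returns LAI per row; rows where the index is undefined are NaN and
    negative predictions are clamped to 0 (the count is logged).
    """
    table = vi_table(reflectance)
    vi = table[model.index_name].to_numpy(float)
    lai = model.predict(vi)
    negative = np.isfinite(lai) & (lai < 0)
    if negative.any():
        logger.info("clamped %d negative LAI predictions to 0", int(negative.sum()))
        lai = np.where(negative, 0.0, lai)
    return pd.Series(lai, index=reflectance.index, name="lai")
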