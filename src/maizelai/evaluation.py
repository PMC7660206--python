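"""Accuracy and heterogeneity statistics.

The accuracy surface follows the fitted-line convention: with estimates L
and field observations L_obs, a least-squares line L_f = a·L + b is fitted
(L independent, L_obs dependent) and

    R² = Σ(L_f,k − L_mean)² / Σ(L_obs,k − L_mean)²,
    RMSE = sqrt(Σ(L_k − L_obs,k)² / n),

with L_mean the mean of the observations.  Note the asymmetry, kept
deliberately: R² is computed from the fitted values while RMSE uses the
raw estimates, so a constant offset leaves R² at 1 but shows up fully in
the RMSE.  For the stated least-squares fit this R² equals the squared
Pearson correlation of L and L_obs.  Spatial heterogeneity uses the
coefficient of variation CV = SD/mean·100% with the sample SD (n − 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InputError, UndefinedValueError
from .indices import significance_class

__all__ = ["EvalResult", "CVResult", "evaluate", "cv_percent", "stagewise_report"]


@dataclass(frozen=True)
class EvalResult:
    """Accuracy of one estimate set against field observations."""

    r: float
    r2: float
    rmse: float
    n: int
    significance: str
    slope: float
    intercept: float


@dataclass(frozen=True)
class CVResult:
    cv: float  # percent
    sd: float
    mean: float


def evaluate(estimates, observed) -> EvalResult:
    """Fitted-line R², raw-error RMSE, Pearson r and its significance."""
    est = np.asarray(estimates, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if est.shape != obs.shape:
        raise InputError("estimates and observations must have equal length")
    n = est.size
    if n < 3:
        raise InputError("need at least 3 pairs")
    if np.ptp(obs) == 0:
        raise DegenerateFitError("observations are constant; R² undefined")
    if np.ptp(est) == 0:
        raise DegenerateFitError("estimates are constant; no line can be fitted")
    fit = stats.linregress(est, obs)
    fitted = fit.slope * est + fit.intercept
    obs_mean = obs.mean()
    r2 = float(np.sum((fitted - obs_mean) ** 2) / np.sum((obs - obs_mean) ** 2))
    rmse = float(np.sqrt(np.mean((est - obs) ** 2)))
    r = float(fit.rvalue)
    return EvalResult(
        r=r,
        r2=r2,
        rmse=rmse,
        n=int(n),
        significance=significance_class(r, int(n)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def cv_percent(values) -> CVResult:
    """Coefficient of variation in percent, sample SD over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InputError("need at least 2 values")
    mean = float(v.mean())
    if mean == 0.0:
        raise UndefinedValueError("CV undefined for zero mean")
    sd = float(v.std(ddof=1))
    return CVResult(cv=sd / mean * 100.0, sd=sd, mean=mean)


def stagewise_report(season_frame: pd.DataFrame, field_obs: pd.DataFrame) -> pd.DataFrame:
    """Per-(method, campaign date) accuracy table plus a pooled row.

    ``season_frame`` holds per-quadrat daily estimates with method labels
    (columns quadrat_id, doy, lai, method); ``field_obs`` the campaign
    observations (quadrat_id, doy, lai).  Campaign dates with fewer than 3
    matched quadrats are skipped with a warning.
    """
    merged = season_frame.merge(field_obs, on=["quadrat_id", "doy"], suffixes=("_est", "_obs"))
    rows = []
    for (method, doy), grp in merged.groupby(["method", "doy"]):
        if len(grp) < 3:
            warnings.warn(f"campaign doy {doy}: only {len(grp)} matched quadrats; skipped", RuntimeWarning)
            continue
        try:
            res = evaluate(grp["lai_est"].to_numpy(), grp["lai_obs"].to_numpy())
        except DegenerateFitError:
            warnings.warn(f"degenerate fit for method={method} doy={doy}; skipped", RuntimeWarning)
            continue
        rows.append((method, int(doy), res.r, res.r2, res.rmse, res.n, res.significance))
    if len(merged) >= 3 and np.ptp(merged["lai_obs"]) > 0 and np.ptp(merged["lai_est"]) > 0:
        res = evaluate(merged["lai_est"].to_numpy(), merged["lai_obs"].to_numpy())
        rows.append(("all", -1, res.r, res.r2, res.rmse, res.n, res.significance))
    return pd.DataFrame(rows, columns=["method", "doy", "r", "r2", "rmse", "n", "significance"])
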