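"""Per-date parameter calibration with optimum averaging.

Core crop parameters that cannot be fixed from field measurements are
estimated by minimising the squared error between the simulated and the
observed plot-mean LAI on one campaign date at a time, with a bounded
derivative-free simplex search.  The final value of each free parameter is
the arithmetic mean of the per-date optima — a deliberately simple scheme
that matches how seasonal crop parameters are usually consolidated from
repeated single-date fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .crop import CropParams, SanRecord, WeatherDay, simulate_season
from .errors import InputError

__all__ = ["CalibrationSpec", "CalibrationResult", "calibrate_once", "calibrate_mean"]

#: Parameters calibrated by numerical optimisation in the default setup.
DEFAULT_FREE_PARAMETERS = ("smfcf", "smw", "sm0", "rdmcr", "span")

_EVAL_BUDGET = 200  # objective evaluations per date, restart included


@dataclass(frozen=True)
class CalibrationSpec:
    """What to optimise: free parameters with bounds, dates, observations."""

    free_parameters: dict[str, tuple[float, float]]
    campaign_doys: tuple[int, ...]
    observed_lai: tuple[float, ...]  # plot-mean field LAI per campaign date
    objective: str = "sse_lai"

    def __post_init__(self) -> None:
        if not self.free_parameters:
            raise InputError("at least one free parameter is required")
        valid = {f.name for f in fields(CropParams)}
        for name, (lo, hi) in self.free_parameters.items():
            if name not in valid:
                raise InputError(f"unknown crop parameter {name!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise InputError(f"bounds for {name} must be finite with lower < upper")
        if len(self.campaign_doys) < 1:
            raise InputError("at least one campaign date is required")
        if len(self.campaign_doys) != len(self.observed_lai):
            raise InputError("one observed LAI per campaign date is required")
        if self.objective != "sse_lai":
            raise InputError("only the 'sse_lai' objective is supported")


@dataclass
class CalibrationResult:
    """Per-date optima, their mean, and convergence diagnostics."""

    params: CropParams
    per_date: list[dict[str, float]]
    objectives: list[float]
    budget_exhausted: list[bool]
    bound_active: list[bool]


def _with_values(params: CropParams, names: Sequence[str], values: Sequence[float]) -> CropParams:
    return replace(params, **dict(zip(names, (float(v) for v in values))))


def calibrate_once(
    spec: CalibrationSpec,
    date_index: int,
    params0: CropParams,
    weather: Sequence[WeatherDay],
    san: SanRecord | None = None,
) -> tuple[dict[str, float], float, bool, bool]:
    """Optimise the free parameters against one campaign date.

    Returns ``(optima, objective, budget_exhausted, bound_active)``.  The
    search is a bounded Nelder–Mead with a restart from the incumbent; if
    the evaluation budget runs out the best point so far is returned with
    ``budget_exhausted`` set.
    """
    weather = list(weather)
    doys = [w.doy for w in weather]
    target_doy = spec.campaign_doys[date_index]
    if target_doy not in doys:
        raise InputError(f"campaign doy {target_doy} outside the weather span")
    day_idx = doys.index(target_doy)
    obs = spec.observed_lai[date_index]
    names = list(spec.free_parameters)
    bounds = [spec.free_parameters[n] for n in names]
    x0 = np.array([np.clip(getattr(params0, n), lo, hi) for n, (lo, hi) in zip(names, bounds)])

    def objective(x: np.ndarray) -> float:
        try:
            p = _with_values(params0, names, x)
        except ValueError:
            return 1e12  # inconsistent parameter combination inside the box
        sim = simulate_season(p, weather, san=san)
        return float((sim.lai[day_idx] - obs) ** 2)

    opts = dict(xatol=1e-6, fatol=1e-12)
    res1 = optimize.minimize(
        objective, x0, method="Nelder-Mead", bounds=bounds,
        options={**opts, "maxfev": int(0.6 * _EVAL_BUDGET)},
    )
    res2 = optimize.minimize(
        objective, res1.x, method="Nelder-Mead", bounds=bounds,
        options={**opts, "maxfev": max(20, _EVAL_BUDGET - res1.nfev)},
    )
    best = res2 if res2.fun <= res1.fun else res1
    exhausted = not (res1.success or res2.success)
    if exhausted:
        warnings.warn(
            f"optimizer budget exhausted for doy {target_doy}; returning best-so-far",
            RuntimeWarning,
        )
    tol = 1e-8
    bound_active = any(
        abs(v - lo) <= tol * max(1.0, abs(lo)) or abs(v - hi) <= tol * max(1.0, abs(hi))
        for v, (lo, hi) in zip(best.x, bounds)
    )
    return dict(zip(names, map(float, best.x))), float(best.fun), exhausted, bound_active


def calibrate_mean(
    spec: CalibrationSpec,
    params0: CropParams,
    weather: Sequence[WeatherDay],
    san: SanRecord | None = None,
) -> CalibrationResult:
    """Run the per-date optimisation on every campaign date and average.

    Each free parameter's final value is the arithmetic mean of its
    per-date optima; all other parameters pass through unchanged.
    """
    per_date, objectives, exhausted, actives = [], [], [], []
    for i in range(len(spec.campaign_doys)):
        try:
            opt, obj, ex, ba = calibrate_once(spec, i, params0, weather, san=san)
        except Exception as err:  # noqa: BLE001 - carry completed dates
            raise InputError(
                f"calibration failed on campaign index {i} "
                f"(completed {len(per_date)} dates: {per_date})"
            ) from err
        per_date.append(opt)
        objectives.append(obj)
        exhausted.append(ex)
        actives.append(ba)
    names = list(spec.free_parameters)
    means = {n: float(np.mean([d[n] for d in per_date])) for n in names}
    return CalibrationResult(
        params=_with_values(params0, names, [means[n] for n in names]),
        per_date=per_date,
        objectives=objectives,
        budget_exhausted=exhausted,
        bound_active=actives,
    )
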