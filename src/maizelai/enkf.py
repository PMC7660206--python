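"""Ensemble Kalman Filter with a gain-expansion divergence guard.

The filter couples daily remote-sensing LAI observations to a daily crop
model: each ensemble member carries a full mechanistic state, is advanced
independently (forecast), and on observation days is corrected with the
classic perturbed-observation analysis

    A_a = A_f + K (D_t − H A_f),    K = A_c Hᵀ (H A_c Hᵀ + D_c)⁻¹,

where A_c and D_c are sample covariances with divisor N − 1.  Because a
small ensemble without process noise tends to collapse and then ignores
observations (filter divergence), the gain can be inflated by an expansion
parameter

    E = R · N_day · σ₁² / (D · σ₂²),

with R ~ U(0, 1), D the window length in days, N_day the current day index,
σ₁² the variance of the remote-sensing LAI series over days 1..N_day and
σ₂² that of the forecast-mean LAI series.  The inflation is applied only
when σ₁²/σ₂² exceeds 4 strictly AND E ≥ 1; the inflated scalar gain is then
clipped so that K·H ≤ 1.

The state vector is green LAI with an identity observation operator; the
machinery is written for arbitrary member objects through a small adapter
so the same window loop runs the crop model and linear toy systems alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from . import crop
from .errors import InputError, NumericalError

__all__ = [
    "Ensemble",
    "ObservationSeries",
    "EnkfConfig",
    "GainRecord",
    "AssimilationResult",
    "ModelAdapter",
    "CropEnsembleAdapter",
    "CallableAdapter",
    "ensemble_covariance",
    "kalman_gain",
    "analysis_update",
    "expansion_parameter",
    "initial_lai_ensemble",
    "assimilate_window",
]


@dataclass
class Ensemble:
    """A_t = (x₁, …, x_N): the member states of the filter."""

    members: list

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ObservationSeries:
    """Dated LAI observations with a common uncertainty."""

    doys: np.ndarray
    lai: np.ndarray
    obs_noise_sd: float | None = None  # absolute sd; None -> relative from config

    def __post_init__(self) -> None:
        doys = np.asarray(self.doys, dtype=int)
        lai = np.asarray(self.lai, dtype=float)
        object.__setattr__(self, "doys", doys)
        object.__setattr__(self, "lai", lai)
        if doys.shape != lai.shape:
            raise InputError("doys and lai must have equal length")
        if doys.size and np.any(np.diff(doys) <= 0):
            raise InputError("observation doys must be strictly increasing")
        if np.any(lai < 0):
            raise InputError("observed LAI must be non-negative")

    def as_dict(self) -> dict[int, float]:
        return {int(d): float(v) for d, v in zip(self.doys, self.lai)}


@dataclass(frozen=True)
class EnkfConfig:
    """Filter configuration; nothing here is a calibrated quantity."""

    n_members: int = 50
    init_spread: float = 0.10  # multiplicative lognormal sd on initial LAI
    process_noise_frac: float = 0.05  # additive Gaussian sd as fraction of LAI
    process_noise_sd: float = 0.0  # absolute additive Gaussian sd
    obs_noise_frac: float = 0.10  # observation-ensemble sd as fraction of obs
    obs_noise_floor: float = 0.05  # minimum absolute observation sd
    guard: bool = True  # expansion-parameter divergence guard
    h: float = 1.0  # scalar observation operator on LAI
    clip_gain: bool = True  # keep K·H <= 1 after inflation

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise InputError("need at least 2 ensemble members")


def ensemble_covariance(members: np.ndarray) -> np.ndarray:
    """Sample covariance (A_t − Ā)(A_t − Ā)ᵀ/(N − 1) of an (N, d) ensemble."""
    a = np.atleast_2d(np.asarray(members, dtype=float))
    if a.shape[0] == 1:
        a = a.T  # a 1-D input is N scalar members
    n = a.shape[0]
    if n < 2:
        raise InputError("covariance needs at least 2 members")
    dev = a - a.mean(axis=0)
    return dev.T @ dev / (n - 1)


def kalman_gain(a_c: np.ndarray, d_c: np.ndarray, h: np.ndarray) -> np.ndarray:
    """K = A_c Hᵀ (H A_c Hᵀ + D_c)⁻¹ for conformable covariance blocks."""
    a_c = np.atleast_2d(np.asarray(a_c, dtype=float))
    d_c = np.atleast_2d(np.asarray(d_c, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    innov = h @ a_c @ h.T + d_c
    cond = np.linalg.cond(innov)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(f"innovation covariance is singular (condition number {cond:.3g})")
    return a_c @ h.T @ np.linalg.inv(innov)


def analysis_update(a_f: np.ndarray, d_t: np.ndarray, k: float | np.ndarray, h: float | np.ndarray) -> np.ndarray:
    """Member-wise A_a = A_f + K (D_t − H A_f); LAI floored at 0.

    For the scalar-LAI state, ``a_f`` and ``d_t`` are length-N vectors.
    """
    a_f = np.asarray(a_f, dtype=float)
    d_t = np.asarray(d_t, dtype=float)
    if a_f.shape != d_t.shape:
        raise InputError("forecast and observed ensembles must be conformable")
    k = float(np.asarray(k).reshape(()))
    h = float(np.asarray(h).reshape(()))
    return np.maximum(0.0, a_f + k * (d_t - h * a_f))


def expansion_parameter(
    rng_draw: float,
    window_days: int,
    day_index: int,
    sigma1_sq: float,
    sigma2_sq: float,
) -> tuple[float, bool]:
    """Gain-expansion factor E = R·N_day·σ₁²/(D·σ₂²) and its trigger.

    Returns ``(E, applied)``; ``applied`` is True only when σ₁²/σ₂² > 4
    strictly AND E ≥ 1.  A vanished model variance disables the guard with
    a warning (divergence by collapse of the forecast series).
    """
    if not (0.0 < rng_draw < 1.0):
        raise InputError("the random draw R must lie in (0, 1)")
    if not (1 <= day_index <= window_days):
        raise InputError("need 1 <= day_index <= window_days")
    if sigma2_sq <= 0.0:
        warnings.warn("model LAI variance is zero; expansion guard skipped", RuntimeWarning)
        return float("nan"), False
    e = rng_draw * day_index * sigma1_sq / (window_days * sigma2_sq)
    applied = (sigma1_sq / sigma2_sq > 4.0) and (e >= 1.0)
    return e, applied


class ModelAdapter(Protocol):
    """Minimal surface the window loop needs from a forecast model."""

    def step(self, member, t: int): ...

    def get_lai(self, member) -> float: ...

    def with_lai(self, member, lai: float): ...


@dataclass
class CropEnsembleAdapter:
    """Adapter advancing full crop states and rescaling them to analysed LAI."""

    params: crop.CropParams
    weather: Sequence[crop.WeatherDay]
    san: crop.SanRecord | None = None

    def step(self, member: crop.CropState, t: int) -> crop.CropState:
        stress = crop.stress_factors(member.sm, self.san, self.params)
        return crop.advance_day(member, self.weather[t], stress, self.params)

    def get_lai(self, member: crop.CropState) -> float:
        return member.lai_green

    def with_lai(self, member: crop.CropState, lai: float) -> crop.CropState:
        return crop.rescale_lai(member, lai)


@dataclass
class CallableAdapter:
    """Adapter for scalar toy dynamics x_t = f(x_{t-1}, t)."""

    fn: Callable[[float, int], float]

    def step(self, member: float, t: int) -> float:
        return self.fn(member, t)

    def get_lai(self, member: float) -> float:
        return float(member)

    def with_lai(self, member: float, lai: float) -> float:
        return float(lai)


def initial_lai_ensemble(
    state,
    adapter: ModelAdapter,
    config: EnkfConfig,
    rng: np.random.Generator,
) -> Ensemble:
    """Multiplicative lognormal perturbation of the initial state's LAI."""
    lai0 = adapter.get_lai(state)
    factors = np.exp(rng.normal(0.0, config.init_spread, config.n_members))
    return Ensemble(members=[adapter.with_lai(state, lai0 * f) for f in factors])


@dataclass
class GainRecord:
    """Per-update diagnostics of the filter."""

    doy: int
    gain: float
    a_c: float
    d_c: float
    sigma1_sq: float
    sigma2_sq: float
    expansion: float
    applied: bool
    rng_draw: float
    window_days: int
    day_index: int


@dataclass
class AssimilationResult:
    """Daily analysis-mean trajectory with the gain log."""

    doys: np.ndarray
    mean_lai: np.ndarray
    gain_records: list[GainRecord] = field(default_factory=list)
    final_members: list = field(default_factory=list)
    captured: dict[int, list] = field(default_factory=dict)

    def gain_log(self) -> pd.DataFrame:
        return pd.DataFrame([vars(g) for g in self.gain_records])


def assimilate_window(
    ensemble: Ensemble,
    adapter: ModelAdapter,
    doys: Sequence[int],
    obs: ObservationSeries | None,
    config: EnkfConfig,
    rng: np.random.Generator,
    capture_days: set[int] | None = None,
) -> AssimilationResult:
    """Run the forecast/update loop over a window of days.

    ``doys[t]`` is the calendar day the adapter's ``step(member, t)``
    advances to.  On days carrying an observation the ensemble is updated;
    otherwise the forecast stands.  ``capture_days`` (window indices)
    collects the full member list after the update on those days, which the
    hybrid method uses to branch a free run off the analysed state.
    Identical seeds give bit-identical output.
    """
    doys = np.asarray(doys, dtype=int)
    n_days = int(doys.size)
    if n_days == 0:
        raise InputError("empty assimilation window")
    obs_map = obs.as_dict() if obs is not None else {}
    if not any(int(d) in obs_map for d in doys):
        warnings.warn("no observations in window; returning the pure forecast", RuntimeWarning)

    members = list(ensemble.members)
    n = len(members)
    mean_lai = np.empty(n_days)
    rs_hist: list[float] = []
    fc_hist: list[float] = []
    records: list[GainRecord] = []
    captured: dict[int, list] = {}

    for t in range(n_days):
        doy = int(doys[t])
        members = [adapter.step(m, t) for m in members]
        lai = np.array([adapter.get_lai(m) for m in members])
        if config.process_noise_frac > 0.0 or config.process_noise_sd > 0.0:
            sd = config.process_noise_frac * np.abs(lai) + config.process_noise_sd
            lai = np.maximum(0.0, lai + rng.normal(0.0, 1.0, n) * sd)
            members = [adapter.with_lai(m, v) for m, v in zip(members, lai)]
        fc_mean = float(lai.mean())

        if doy in obs_map:
            obs_val = obs_map[doy]
            rs_hist.append(obs_val)
            fc_hist.append(fc_mean)
            sigma1_sq = float(np.var(rs_hist, ddof=1)) if len(rs_hist) > 1 else 0.0
            sigma2_sq = float(np.var(fc_hist, ddof=1)) if len(fc_hist) > 1 else 0.0

            if obs.obs_noise_sd is not None:
                obs_sd = obs.obs_noise_sd
            else:
                obs_sd = max(config.obs_noise_frac * obs_val, config.obs_noise_floor)
            d_t = obs_val + rng.normal(0.0, obs_sd, n)

            a_c = float(np.var(lai, ddof=1))
            d_c = float(np.var(d_t, ddof=1))
            innov = config.h * a_c * config.h + d_c
            if innov <= 0.0:
                warnings.warn("zero innovation covariance; update skipped", RuntimeWarning)
                gain = 0.0
                e_val, applied, r_draw = float("nan"), False, float("nan")
            else:
                gain = a_c * config.h / innov
                e_val, applied, r_draw = float("nan"), False, float("nan")
                if config.guard:
                    r_draw = float(rng.uniform(0.0, 1.0))
                    if sigma2_sq > 0.0:
                        e_val, applied = expansion_parameter(r_draw, n_days, t + 1, sigma1_sq, sigma2_sq)
                    if applied:
                        gain *= e_val
                if config.clip_gain:
                    gain = min(gain, 1.0 / config.h)
                lai = analysis_update(lai, d_t, gain, config.h)
                members = [adapter.with_lai(m, v) for m, v in zip(members, lai)]
            records.append(
                GainRecord(
                    doy=doy,
                    gain=gain,
                    a_c=a_c,
                    d_c=d_c,
                    sigma1_sq=sigma1_sq,
                    sigma2_sq=sigma2_sq,
                    expansion=e_val,
                    applied=applied,
                    rng_draw=r_draw,
                    window_days=n_days,
                    day_index=t + 1,
                )
            )
        mean_lai[t] = float(lai.mean())
        if capture_days and t in capture_days:
            captured[t] = list(members)

    return AssimilationResult(
        doys=doys,
        mean_lai=mean_lai,
        gain_records=records,
        final_members=members,
        captured=captured,
    )
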