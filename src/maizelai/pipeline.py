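"""Three-stage full-season LAI estimation.

The season is split at the midpoints between the three field campaigns
into an early, a mid and a late stage.  Each stage gets the estimator that
copes best with its data regime:

* early — the per-date empirical index model (canopy still unsaturated);
* mid — ensemble Kalman assimilation of daily remote-sensing LAI into the
  crop model (rainy-season gaps tolerated);
* late — the hybrid method: assimilate until the crop reaches anthesis
  (DVS = 1), then let the calibrated model free-run to season end, so the
  saturated, senescence-contaminated late-season reflectance never touches
  the estimate.

Remote-sensing LAI is made daily by inverse-distance weighting in time of
the per-survey-date model predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import crop, enkf, indices
from .errors import InputError

__all__ = [
    "StageConfig",
    "SeasonResult",
    "HybridResult",
    "delimit_stages",
    "idw_daily",
    "first_dvs1_index",
    "run_hybrid",
    "run_combined",
]


@dataclass(frozen=True)
class StageConfig:
    """Calendar stage boundaries (inclusive as printed).

    ``early_end_doy`` is the last early-stage day; ``late_start_doy`` the
    first late-stage day.
    """

    early_end_doy: int
    late_start_doy: int

    def __post_init__(self) -> None:
        if self.early_end_doy >= self.late_start_doy:
            raise InputError("early_end must precede late_start")

    def label(self, doy: int) -> str:
        if doy <= self.early_end_doy:
            return "vi"
        if doy < self.late_start_doy:
            return "assimilation"
        return "hybrid"


def delimit_stages(campaign_doys: Sequence[int]) -> StageConfig:
    """Stage boundaries from the midpoints of the field campaigns.

    The early stage ends at the floor of the midpoint of campaigns 1–2;
    the late stage starts at the ceiling of the midpoint of campaigns 2–3
    (so a half-day midpoint always falls in the mid stage on both sides).
    """
    doys = list(campaign_doys)
    if len(doys) < 3:
        raise InputError("need at least 3 campaign dates")
    if doys != sorted(doys):
        raise InputError("campaign dates must be sorted ascending")
    early_end = math.floor((doys[0] + doys[1]) / 2.0)
    late_start = math.ceil((doys[1] + doys[2]) / 2.0)
    return StageConfig(early_end_doy=early_end, late_start_doy=late_start)


def idw_daily(
    obs_doys: Sequence[int],
    obs_lai: Sequence[float],
    target_doys: Sequence[int],
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance weighting in time onto a daily grid.

    Exact pass-through at observation days; default power 2.
    """
    obs_doys = np.asarray(obs_doys, dtype=float)
    obs_lai = np.asarray(obs_lai, dtype=float)
    if obs_doys.size == 0:
        raise InputError("no observations to interpolate")
    if obs_doys.shape != obs_lai.shape:
        raise InputError("obs_doys and obs_lai must have equal length")
    if power <= 0:
        raise InputError("power must be positive")
    out = np.empty(len(target_doys))
    for i, t in enumerate(np.asarray(target_doys, dtype=float)):
        dist = np.abs(t - obs_doys)
        hit = dist == 0
        if hit.any():
            out[i] = obs_lai[hit][0]
        else:
            w = dist ** (-power)
            out[i] = float(np.sum(w * obs_lai) / np.sum(w))
    return out


def first_dvs1_index(params: crop.CropParams, weather: Sequence[crop.WeatherDay]) -> int | None:
    """Window index of the first day with DVS ≥ 1 (anthesis).

    Phenology depends only on thermal time, so this is deterministic given
    the weather and identical for every ensemble member.
    """
    tt = 0.0
    for i, w in enumerate(weather):
        tt += max(0.0, 0.5 * (w.tmax + w.tmin) - params.tbase)
        if tt >= params.tsum1:
            return i
    return None


@dataclass
class HybridResult:
    """Assimilate-then-free-run trajectory."""

    doys: np.ndarray
    lai: np.ndarray
    switch_index: int | None  # window index of the first free-run day
    switch_state: crop.CropState | None  # analysis-mean state the free run starts from
    gain_log: pd.DataFrame
    mode: str  # "hybrid" | "free_run" | "assimilation_only"


def run_hybrid(
    params: crop.CropParams,
    weather: Sequence[crop.WeatherDay],
    san: crop.SanRecord | None,
    daily_obs: enkf.ObservationSeries | None,
    config: enkf.EnkfConfig,
    seed: int | np.random.SeedSequence = 0,
    switch_rule: str = "dvs>=1",
    late_start_doy: int | None = None,
    init: crop.CropState | None = None,
) -> HybridResult:
    """Assimilate until the switch day, then free-run the crop model.

    The switch is the first day the (deterministic) phenology reaches
    DVS = 1; if it is never reached, the calendar ``late_start_doy`` is the
    fallback, and failing that the full-season assimilation is returned
    with a warning.  With no observations at all the result is exactly the
    deterministic season simulation.
    """
    weather = list(weather)
    doys = np.array([w.doy for w in weather])
    if daily_obs is None or daily_obs.doys.size == 0:
        warnings.warn("no observations; hybrid degenerates to the free-running model", RuntimeWarning)
        sim = crop.simulate_season(params, weather, san=san, init=init)
        return HybridResult(
            doys=doys, lai=sim.lai, switch_index=0,
            switch_state=init if init is not None else crop.initial_state(params, int(doys[0])),
            gain_log=pd.DataFrame(), mode="free_run",
        )

    if switch_rule == "dvs>=1":
        switch = first_dvs1_index(params, weather)
        if switch is None:
            switch = None if late_start_doy is None else int(np.searchsorted(doys, late_start_doy))
    elif switch_rule == "doy":
        if late_start_doy is None:
            raise InputError("switch_rule 'doy' needs late_start_doy")
        switch = int(np.searchsorted(doys, late_start_doy))
    else:
        raise InputError(f"unknown switch rule {switch_rule!r}")
    if switch is None or switch >= len(weather):
        warnings.warn("switch never reached; returning full-season assimilation", RuntimeWarning)
        switch = None

    rng = np.random.default_rng(seed)
    adapter = enkf.CropEnsembleAdapter(params=params, weather=weather, san=san)
    state0 = init if init is not None else crop.initial_state(params, int(doys[0]))
    ens = enkf.initial_lai_ensemble(state0, adapter, config, rng)

    if switch is None:
        res = enkf.assimilate_window(ens, adapter, doys, daily_obs, config, rng)
        return HybridResult(
            doys=doys, lai=res.mean_lai, switch_index=None, switch_state=None,
            gain_log=res.gain_log(), mode="assimilation_only",
        )

    res = enkf.assimilate_window(
        ens, adapter, doys[: switch + 1], daily_obs, config, rng, capture_days={switch},
    )
    switch_state = crop.ensemble_mean_state(res.captured[switch])
    free = crop.simulate_season(params, weather[switch + 1 :], san=san, init=switch_state)
    lai = np.concatenate([res.mean_lai, free.lai])
    return HybridResult(
        doys=doys, lai=lai, switch_index=switch, switch_state=switch_state,
        gain_log=res.gain_log(), mode="hybrid",
    )


@dataclass
class SeasonResult:
    """Combined full-season estimate with per-day method labels."""

    frame: pd.DataFrame  # quadrat_id, doy, lai, method
    gain_log: pd.DataFrame
    models: dict[int, indices.LinearVIModel]
    stages: StageConfig
    provenance: dict = field(default_factory=dict)

    def series_for(self, quadrat_id: str) -> pd.DataFrame:
        return self.frame[self.frame.quadrat_id == quadrat_id].reset_index(drop=True)


def _fit_campaign_models(
    reflectance: pd.DataFrame,
    field_obs: pd.DataFrame,
    campaign_doys: Sequence[int],
) -> dict[int, indices.LinearVIModel]:
    """One best-index linear model per campaign date."""
    models: dict[int, indices.LinearVIModel] = {}
    for d in campaign_doys:
        refl_d = reflectance[reflectance.doy == d]
        obs_d = field_obs[field_obs.doy == d]
        merged = refl_d.merge(obs_d, on="quadrat_id", suffixes=("", "_obs"))
        if len(merged) < 3:
            raise InputError(f"campaign doy {d}: fewer than 3 matched quadrats")
        vis = indices.vi_table(merged[list(indices.BAND_NAMES)].assign())
        fits = {
            name: indices.fit_linear_model(vis[name].to_numpy(), merged["lai"].to_numpy(), name)
            for name in indices.INDEX_ORDER
            if np.isfinite(vis[name]).all() and np.ptp(vis[name].to_numpy()) > 0
        }
        best = indices.select_best_vi(fits)
        models[int(d)] = fits[best]
    return models


def rs_lai_table(
    reflectance: pd.DataFrame,
    models: dict[int, indices.LinearVIModel],
) -> pd.DataFrame:
    """Per-quadrat, per-survey-date LAI from the nearest-in-time model."""
    model_doys = np.array(sorted(models))
    rows = []
    for d, group in reflectance.groupby("doy"):
        nearest = int(model_doys[np.argmin(np.abs(model_doys - int(d)))])
        lai = indices.estimate_lai_map(group[list(indices.BAND_NAMES)], models[nearest])
        for qid, v in zip(group["quadrat_id"], lai):
            rows.append((qid, int(d), float(v)))
    return pd.DataFrame(rows, columns=["quadrat_id", "doy", "lai"])


def run_combined(
    params: crop.CropParams,
    weather: Sequence[crop.WeatherDay],
    san: Sequence[crop.SanRecord],
    reflectance: pd.DataFrame,
    field_obs: pd.DataFrame,
    campaign_doys: Sequence[int],
    config: enkf.EnkfConfig | None = None,
    seed: int = 0,
    stages: StageConfig | None = None,
) -> SeasonResult:
    """Run the full three-stage estimator for every quadrat.

    Steps: fit per-campaign empirical models and select the best index per
    date; predict LAI on every survey date with the nearest-in-time model;
    interpolate to daily remote-sensing LAI; assimilate it into the crop
    model per quadrat; branch the hybrid free run at DVS = 1; and stitch
    the season as vi | assimilation | hybrid by the stage boundaries.
    A single seed governs all stochastic parts.
    """
    weather = list(weather)
    config = config or enkf.EnkfConfig()
    stages = stages or delimit_stages(campaign_doys)
    doys = np.array([w.doy for w in weather])
    last_doy = int(doys[-1])

    early_doys = doys[doys <= stages.early_end_doy]
    rs_days = set(reflectance.doy.astype(int))
    if not rs_days & set(map(int, early_doys)):
        raise InputError(
            f"no reflectance in the early window (doys {early_doys.min()}..{early_doys.max()})"
        )

    models = _fit_campaign_models(reflectance, field_obs, campaign_doys)
    rs_lai = rs_lai_table(reflectance, models)

    switch = first_dvs1_index(params, weather)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(san))

    frames = []
    gain_logs = []
    for rec, child in zip(san, children):
        q_rs = rs_lai[rs_lai.quadrat_id == rec.quadrat_id].sort_values("doy")
        daily = idw_daily(q_rs.doy.to_numpy(), q_rs.lai.to_numpy(), doys)
        obs = enkf.ObservationSeries(doys=doys, lai=np.maximum(0.0, daily))

        rng = np.random.default_rng(child)
        adapter = enkf.CropEnsembleAdapter(params=params, weather=weather, san=rec)
        ens = enkf.initial_lai_ensemble(crop.initial_state(params, int(doys[0])), adapter, config, rng)
        capture = {switch} if switch is not None else None
        res = enkf.assimilate_window(ens, adapter, doys, obs, config, rng, capture_days=capture)

        if switch is not None and switch < len(weather) - 1:
            switch_state = crop.ensemble_mean_state(res.captured[switch])
            free = crop.simulate_season(params, weather[switch + 1 :], san=rec, init=switch_state)
            hybrid_lai = np.concatenate([res.mean_lai[: switch + 1], free.lai])
        else:
            if stages.late_start_doy <= last_doy:
                warnings.warn("DVS=1 not reached; late stage falls back to assimilation", RuntimeWarning)
            hybrid_lai = res.mean_lai

        lai_out = np.empty(len(doys))
        labels = []
        for i, d in enumerate(map(int, doys)):
            lab = stages.label(d)
            labels.append(lab)
            if lab == "vi":
                lai_out[i] = daily[i]
            elif lab == "assimilation":
                lai_out[i] = res.mean_lai[i]
            else:
                lai_out[i] = hybrid_lai[i]
        frames.append(
            pd.DataFrame(
                {"quadrat_id": rec.quadrat_id, "doy": doys, "lai": lai_out, "method": labels}
            )
        )
        log = res.gain_log()
        if not log.empty:
            log.insert(0, "quadrat_id", rec.quadrat_id)
        gain_logs.append(log)

    return SeasonResult(
        frame=pd.concat(frames, ignore_index=True),
        gain_log=pd.concat([g for g in gain_logs if not g.empty], ignore_index=True)
        if any(not g.empty for g in gain_logs)
        else pd.DataFrame(),
        models=models,
        stages=stages,
        provenance={"seed": seed, "n_members": config.n_members, "switch_index": switch},
    )
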