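"""Synthetic study-condition generator.

Emulates one spring-maize season in a cold-temperate monsoon climate
(emergence around 1 June, harvest mid-October): daily weather, per-quadrat
soil available nutrients, "true" green/brown LAI seasons from the crop
simulator, five-band canopy reflectance with asymptotic saturation and a
late-season brown-leaf signal, and noisy dated field LAI campaigns.

The reflectance model is Beer–Lambert style soil/leaf mixing: per band b

    ρ_b = ρ_soil,b + (ρ_mix,b − ρ_soil,b)·(1 − exp(−k_b·LAI_total)) + ε,

with ρ_mix,b the green/brown leaf asymptote mixture weighted by the
green/brown LAI fractions.  It reproduces the two behaviours that break
index-based LAI retrieval late in the season — saturation of the signal at
high LAI and the spectral shift of senescing leaves — without attempting
radiative transfer.

All randomness flows from a single seed through named, stable substreams,
so identical seeds give bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .crop import CropParams, SanRecord, SimResult, WeatherDay, simulate_season
from .errors import InputError

__all__ = [
    "WeatherConfig",
    "SceneParams",
    "gen_weather",
    "gen_san",
    "synth_reflectance",
    "gen_truth_and_obs",
    "TruthAndObs",
    "DEFAULT_CAMPAIGN_DOYS",
    "DEFAULT_RS_DOYS",
    "write_weather_csv",
    "read_weather_csv",
    "write_san_csv",
    "read_san_csv",
    "write_observations_csv",
    "read_observations_csv",
    "write_reflectance_csv",
    "read_reflectance_csv",
]

#: Field campaigns on 30 June, 29 July and 25 August (non-leap year DOYs).
DEFAULT_CAMPAIGN_DOYS = (181, 210, 237)
#: Flight dates of the multispectral surveys (six, ending 25 August).
DEFAULT_RS_DOYS = (165, 181, 196, 210, 224, 237)

_BANDS = ("blue", "green", "red", "rededge", "nir")


@dataclass(frozen=True)
class WeatherConfig:
    """Seasonal climate the weather generator draws around."""

    tmean_base: float = 12.0  # °C annual-mean level
    tmean_amp: float = 10.5  # °C seasonal amplitude
    tmean_peak_doy: int = 200  # warmest day of year
    diurnal_half_range: float = 5.0  # °C, (tmax - tmin)/2 before noise
    temp_noise_sd: float = 1.8  # °C day-to-day noise
    rad_base: float = 16.0  # MJ m⁻² d⁻¹
    rad_amp: float = 7.0
    rad_peak_doy: int = 172
    rad_noise_sd: float = 3.0
    wet_day_prob: float = 0.35
    rain_shape: float = 1.2  # gamma shape of wet-day totals
    rain_scale: float = 8.0  # mm

    def seasonal_tmean(self, doys) -> np.ndarray:
        doys = np.asarray(doys, dtype=float)
        return self.tmean_base + self.tmean_amp * np.cos(
            2.0 * np.pi * (doys - self.tmean_peak_doy) / 365.0
        )


def gen_weather(
    n_days: int,
    start_doy: int = 152,
    seed: int = 0,
    config: WeatherConfig | None = None,
) -> list[WeatherDay]:
    """Generate a daily weather series.

    Sinusoidal seasonal means plus bounded noise; tmax ≥ tmin is enforced
    by construction (half the diurnal range never drops below 0.5 °C).
    """
    if n_days < 1:
        raise InputError("n_days must be positive")
    cfg = config or WeatherConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    doys = np.arange(start_doy, start_doy + n_days)
    tmean = cfg.seasonal_tmean(doys) + rng.normal(0.0, cfg.temp_noise_sd, n_days)
    half = np.maximum(0.5, cfg.diurnal_half_range + rng.normal(0.0, 1.0, n_days))
    rad = cfg.rad_base + cfg.rad_amp * np.cos(2.0 * np.pi * (doys - cfg.rad_peak_doy) / 365.0)
    rad = np.maximum(1.0, rad + rng.normal(0.0, cfg.rad_noise_sd, n_days))
    wet = rng.random(n_days) < cfg.wet_day_prob
    rain = np.where(wet, rng.gamma(cfg.rain_shape, cfg.rain_scale, n_days), 0.0)
    return [
        WeatherDay(
            doy=int(d),
            tmin=float(t - h),
            tmax=float(t + h),
            radiation=float(r),
            precip=float(p),
        )
        for d, t, h, r, p in zip(doys, tmean, half, rad, rain)
    ]


#: Calibrated spans of soil available N/P/K across the field (mg/kg).
SAN_RANGES = {"n": (40.0, 410.0), "p": (10.0, 80.0), "k": (20.0, 340.0)}


def gen_san(n_quadrats: int, seed: int = 0) -> list[SanRecord]:
    """Per-quadrat soil available nutrients, uniform over the field spans."""
    if n_quadrats < 1:
        raise InputError("n_quadrats must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    records = []
    for i in range(n_quadrats):
        records.append(
            SanRecord(
                quadrat_id=f"Q{i + 1:02d}",
                n_avail=float(rng.uniform(*SAN_RANGES["n"])),
                p_avail=float(rng.uniform(*SAN_RANGES["p"])),
                k_avail=float(rng.uniform(*SAN_RANGES["k"])),
            )
        )
    return records


@dataclass(frozen=True)
class SceneParams:
    """Optical configuration of the synthetic reflectance scene.

    Band order is (blue, green, red, rededge, nir).  Asymptotes are the
    reflectance of an optically thick pure green or brown canopy; the soil
    line is what a bare pixel shows.  These are generator configuration
    chosen for qualitative realism, not field-calibrated values.
    """

    rho_soil: tuple[float, ...] = (0.06, 0.09, 0.12, 0.18, 0.22)
    rho_green: tuple[float, ...] = (0.03, 0.10, 0.05, 0.30, 0.45)
    rho_brown: tuple[float, ...] = (0.08, 0.15, 0.20, 0.28, 0.25)
    k_b: tuple[float, ...] = (0.55, 0.50, 0.60, 0.45, 0.40)
    refl_noise_sd: float = 0.01
    lai_obs_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_soil", "rho_green", "rho_brown"):
            if any(not (0.0 < v < 1.0) for v in getattr(self, name)):
                raise InputError(f"{name} values must lie in (0, 1)")
        if any(k <= 0 for k in self.k_b):
            raise InputError("extinction coefficients must be positive")
        if self.refl_noise_sd < 0 or self.lai_obs_noise_sd < 0:
            raise InputError("noise standard deviations must be non-negative")


def synth_reflectance(
    lai_green: float,
    lai_brown: float,
    scene: SceneParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Five-band reflectance of a mixed green/brown canopy over soil.

    Returns an array in band order (blue, green, red, rededge, nir),
    clipped to (0, 1).  With ``refl_noise_sd = 0`` the evaluation is exact.
    """
    if lai_green < 0 or lai_brown < 0:
        raise InputError("LAI components must be non-negative")
    total = lai_green + lai_brown
    soil = np.asarray(scene.rho_soil)
    green = np.asarray(scene.rho_green)
    brown = np.asarray(scene.rho_brown)
    k = np.asarray(scene.k_b)
    if total == 0.0:
        rho = soil.copy()
    else:
        mix = (lai_green * green + lai_brown * brown) / total
        rho = soil + (mix - soil) * (1.0 - np.exp(-k * total))
    if scene.refl_noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng(scene.seed)
        rho = rho + rng.normal(0.0, scene.refl_noise_sd, rho.shape)
    eps = 1e-9
    return np.clip(rho, eps, 1.0 - eps)


@dataclass
class TruthAndObs:
    """One synthetic scene: per-quadrat truth, field campaigns, reflectance."""

    truth: pd.DataFrame  # quadrat_id, doy, lai_green, lai_brown, dvs
    field_obs: pd.DataFrame  # quadrat_id, doy, lai
    reflectance: pd.DataFrame  # quadrat_id, doy, blue..nir
    san: list[SanRecord]
    weather: list[WeatherDay]
    sims: dict[str, SimResult] = field(default_factory=dict)

    def truth_for(self, quadrat_id: str) -> pd.DataFrame:
        return self.truth[self.truth.quadrat_id == quadrat_id].reset_index(drop=True)

    def plot_mean_truth(self) -> pd.DataFrame:
        return self.truth.groupby("doy", as_index=False)[["lai_green", "lai_brown"]].mean()


def gen_truth_and_obs(
    params: CropParams,
    weather: Sequence[WeatherDay],
    san: Sequence[SanRecord],
    campaign_doys: Sequence[int] = DEFAULT_CAMPAIGN_DOYS,
    scene: SceneParams | None = None,
    rs_doys: Sequence[int] = DEFAULT_RS_DOYS,
) -> TruthAndObs:
    """Simulate per-quadrat truth and sample noisy observations from it.

    True green LAI comes from the crop simulator under each quadrat's
    nutrient limitation; brown LAI is the senesced leaf area the simulator
    accumulates after cohort death (so the brown signal rises once the crop
    passes anthesis).  Field LAI = truth + Gaussian noise truncated at 0 on
    the campaign dates; reflectance is sampled on the survey dates.
    """
    scene = scene or SceneParams()
    weather = list(weather)
    season = {w.doy for w in weather}
    for d in list(campaign_doys) + list(rs_doys):
        if d not in season:
            raise InputError(f"date doy={d} outside the weather span")
    ss = np.random.SeedSequence(scene.seed, spawn_key=(2,))
    truth_rows, obs_rows, refl_rows = [], [], []
    sims: dict[str, SimResult] = {}
    doys = np.array([w.doy for w in weather])
    for rec, child in zip(san, ss.spawn(len(san))):
        rng = np.random.default_rng(child)
        sim = simulate_season(params, weather, san=rec)
        sims[rec.quadrat_id] = sim
        lai_g, lai_b, dvs = sim.lai, sim.lai_brown, sim.dvs
        for d, g, b, v in zip(doys, lai_g, lai_b, dvs):
            truth_rows.append((rec.quadrat_id, int(d), float(g), float(b), float(v)))
        idx = {int(d): i for i, d in enumerate(doys)}
        for d in campaign_doys:
            noise = rng.normal(0.0, scene.lai_obs_noise_sd) if scene.lai_obs_noise_sd > 0 else 0.0
            obs_rows.append((rec.quadrat_id, int(d), max(0.0, lai_g[idx[int(d)]] + noise)))
        for d in rs_doys:
            rho = synth_reflectance(lai_g[idx[int(d)]], lai_b[idx[int(d)]], scene, rng=rng)
            refl_rows.append((rec.quadrat_id, int(d), *map(float, rho)))
    return TruthAndObs(
        truth=pd.DataFrame(truth_rows, columns=["quadrat_id", "doy", "lai_green", "lai_brown", "dvs"]),
        field_obs=pd.DataFrame(obs_rows, columns=["quadrat_id", "doy", "lai"]),
        reflectance=pd.DataFrame(refl_rows, columns=["quadrat_id", "doy", *_BANDS]),
        san=list(san),
        weather=weather,
        sims=sims,
    )


# ---------------------------------------------------------------------------
# plain-text writers/readers


def write_weather_csv(weather: Sequence[WeatherDay], path: str | Path) -> None:
    pd.DataFrame(
        [(w.doy, w.tmin, w.tmax, w.radiation, w.precip) for w in weather],
        columns=["doy", "tmin", "tmax", "rad", "precip"],
    ).to_csv(path, index=False)


def read_weather_csv(path: str | Path) -> list[WeatherDay]:
    df = pd.read_csv(path)
    return [
        WeatherDay(doy=int(r.doy), tmin=float(r.tmin), tmax=float(r.tmax), radiation=float(r.rad), precip=float(r.precip))
        for r in df.itertuples()
    ]


def write_observations_csv(field_obs: pd.DataFrame, path: str | Path) -> None:
    field_obs.loc[:, ["quadrat_id", "doy", "lai"]].to_csv(path, index=False)


def read_observations_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"quadrat_id": str})


def write_reflectance_csv(reflectance: pd.DataFrame, path: str | Path) -> None:
    reflectance.loc[:, ["quadrat_id", "doy", *_BANDS]].to_csv(path, index=False)


def read_reflectance_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"quadrat_id": str})


def write_san_csv(records: Sequence[SanRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.quadrat_id, r.n_avail, r.p_avail, r.k_avail) for r in records],
        columns=["quadrat_id", "n_avail", "p_avail", "k_avail"],
    ).to_csv(path, index=False)


def read_san_csv(path: str | Path) -> list[SanRecord]:
    df = pd.read_csv(path)
    return [
        SanRecord(quadrat_id=str(r.quadrat_id), n_avail=float(r.n_avail), p_avail=float(r.p_avail), k_avail=float(r.k_avail))
        for r in df.itertuples()
    ]
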