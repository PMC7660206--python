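"""Reduced-order daily crop-growth simulator for spring maize.

The simulator keeps the parameter semantics of the WOFOST core set that is
sensitive to leaf area index — thermal-time phenology (TSUM1/TSUM2),
DVS-dependent dry-matter partitioning tables, assimilate conversion
efficiencies, leaf life span (SPAN) expressed in days at 35 °C, and a
single-layer soil-moisture bucket — while replacing the full source-sink
photosynthesis scheme with a light-use-efficiency growth equation.  It is a
deliberately small daily process model: green LAI is carried as a set of
leaf cohorts so that senescence removes exactly the leaf area each cohort
contributed, which is what lets an ensemble filter rescale the mechanistic
state to an analysed LAI without breaking the age structure.

State and parameter units follow field conventions: temperatures in °C,
thermal time in °C·d, radiation in MJ m⁻² d⁻¹, biomass pools in kg/ha,
LAI in m²/m², soil moisture in cm³/cm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "SanRecord",
    "CropParams",
    "CropState",
    "StressFactors",
    "WeatherDay",
    "dvs_update",
    "stress_factors",
    "advance_day",
    "initial_state",
    "simulate_season",
    "rescale_lai",
    "ensemble_mean_state",
    "SimResult",
]

# Partition tables are (DVS, fraction) knot pairs, linearly interpolated and
# clamped outside the knot range.
PartitionTable = tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class WeatherDay:
    """One day of driving weather."""

    doy: int
    tmin: float  # °C
    tmax: float  # °C
    radiation: float  # MJ m⁻² d⁻¹, global
    precip: float  # mm

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise InputError(f"tmax {self.tmax} < tmin {self.tmin} on doy {self.doy}")
        if self.radiation < 0 or self.precip < 0:
            raise InputError("radiation and precip must be non-negative")


@dataclass(frozen=True)
class SanRecord:
    """Soil available nutrients of one quadrat (mg/kg)."""

    quadrat_id: str
    n_avail: float
    p_avail: float
    k_avail: float

    def __post_init__(self) -> None:
        if min(self.n_avail, self.p_avail, self.k_avail) <= 0:
            raise InputError("soil available N/P/K must all be positive")


@dataclass(frozen=True)
class StressFactors:
    """Multiplicative growth reduction factors, each in [0, 1]."""

    f_water: float
    f_nutrient: float


def _interp(table: PartitionTable, dvs: float) -> float:
    xs = [k for k, _ in table]
    ys = [v for _, v in table]
    return float(np.interp(dvs, xs, ys))


@dataclass(frozen=True)
class CropParams:
    """Calibrated crop and soil parameters plus surrogate growth constants.

    The first block mirrors the classic WOFOST names; defaults are the
    calibrated spring-maize values.  The second block parameterises the
    reduced-order growth equation itself and is documented configuration,
    not a calibration product.
    """

    # phenology (°C·d)
    tsum1: float = 890.0
    tsum2: float = 710.0
    # conversion efficiencies (kg/kg)
    cvl: float = 0.64
    cvo: float = 0.81
    cvr: float = 0.70
    cvs: float = 0.66
    # dry-matter partitioning vs DVS; above-ground tables sum to 1 per knot
    frtb: PartitionTable = ((0.0, 0.40), (0.6, 0.15), (1.0, 0.05), (1.3, 0.0), (2.0, 0.0))
    fltb: PartitionTable = ((0.0, 0.72), (0.7, 0.50), (1.0, 0.18), (1.4, 0.12), (2.0, 0.00))
    fstb: PartitionTable = ((0.0, 0.28), (0.7, 0.50), (1.0, 0.62), (1.4, 0.19), (2.0, 0.06))
    fotb: PartitionTable = ((0.0, 0.00), (0.7, 0.00), (1.0, 0.20), (1.4, 0.69), (2.0, 0.94))
    # leaf life span in days at 35 °C
    span: float = 28.0
    # soil water retention (cm³/cm³) and rooting depth (m)
    smfcf: float = 0.46
    smw: float = 0.20
    sm0: float = 0.57
    rdmcr: float = 2.4
    # reference soil nutrient contents (mg/kg), used when no quadrat record
    nbase: float = 100.0
    pbase: float = 100.0
    kbase: float = 100.0
    # surrogate growth constants
    tbase: float = 8.0  # °C
    lue: float = 12.5  # kg DM ha⁻¹ per MJ m⁻² intercepted
    sla: float = 0.0022  # ha/kg
    k_ext: float = 0.6  # canopy light extinction
    et_demand: float = 3.5  # mm/d potential crop evapotranspiration
    # nutrient half-saturation constants (mg/kg); 100/9 makes 100 mg/kg -> 0.9
    h_n: float = 100.0 / 9.0
    h_p: float = 100.0 / 9.0
    h_k: float = 100.0 / 9.0

    def __post_init__(self) -> None:
        if self.tsum1 <= 0 or self.tsum2 <= 0:
            raise ConfigurationError("TSUM1 and TSUM2 must be positive")
        if not (0.0 <= self.smw < self.smfcf < self.sm0 <= 1.0):
            raise ConfigurationError("need 0 <= SMW < SMFCF < SM0 <= 1")
        if self.span <= 0:
            raise ConfigurationError("SPAN must be positive")
        if self.tbase >= 35.0:
            raise ConfigurationError("base temperature must be below 35 °C")
        for tab in (self.frtb, self.fltb, self.fstb, self.fotb):
            if any(not (0.0 <= v <= 1.0) for _, v in tab):
                raise ConfigurationError("partition fractions must lie in [0, 1]")
        knots = sorted({k for k, _ in self.fltb} | {k for k, _ in self.fstb} | {k for k, _ in self.fotb})
        for k in knots:
            s = _interp(self.fltb, k) + _interp(self.fstb, k) + _interp(self.fotb, k)
            if abs(s - 1.0) > 1e-9:
                raise ConfigurationError(f"above-ground partition fractions sum to {s} != 1 at DVS={k}")


@dataclass(frozen=True)
class CropState:
    """Daily simulator state.

    ``cohort_age`` is physiological leaf age in SPAN units (days at 35 °C);
    ``cohort_lai`` the green LAI each cohort still contributes.  Biomass
    pools are cumulative dry matter; ``cum_converted`` tracks all converted
    assimilate for mass-balance checks.
    """

    doy: int
    tt: float  # accumulated effective temperature, °C·d
    dvs: float
    cohort_age: np.ndarray
    cohort_lai: np.ndarray
    lai_brown: float
    w_leaf: float
    w_stem: float
    w_storage: float
    w_root: float
    w_leaf_dead: float
    sm: float
    cum_converted: float = 0.0

    @property
    def lai_green(self) -> float:
        return float(self.cohort_lai.sum())


def dvs_update(tt: float, params: CropParams) -> float:
    """Development stage from accumulated effective temperature.

    Piecewise linear in thermal time: 0→1 over TSUM1, 1→2 over TSUM2,
    clamped at 2 (maturity).
    """
    if tt < 0:
        raise InputError("thermal time must be non-negative")
    if tt <= params.tsum1:
        return tt / params.tsum1
    return min(2.0, 1.0 + (tt - params.tsum1) / params.tsum2)


def stress_factors(sm: float, san: SanRecord | None, params: CropParams) -> StressFactors:
    """Water and nutrient growth-reduction factors.

    Water stress ramps linearly between wilting point and field capacity.
    Nutrient limitation is a Liebig minimum over saturating (Michaelis-
    Menten) responses of available N, P and K; it stands in for an explicit
    soil nutrient balance.
    """
    if params.smfcf <= params.smw:
        raise ConfigurationError("SMFCF must exceed SMW")
    f_water = min(1.0, max(0.0, (sm - params.smw) / (params.smfcf - params.smw)))
    if san is None:
        n, p, k = params.nbase, params.pbase, params.kbase
    else:
        n, p, k = san.n_avail, san.p_avail, san.k_avail
    f_nutrient = min(n / (n + params.h_n), p / (p + params.h_p), k / (k + params.h_k))
    return StressFactors(f_water=f_water, f_nutrient=f_nutrient)


def advance_day(
    state: CropState,
    weather: WeatherDay,
    stress: StressFactors,
    params: CropParams,
) -> CropState:
    """Advance the crop state by one day.

    Order of operations: thermal time and DVS; light-use-efficiency gross
    growth scaled by the stress factors; partitioning and conversion into
    the biomass pools; a new leaf cohort from today's leaf growth; cohort
    ageing at Teff/(35 − Tbase) SPAN-days with death past SPAN; and the
    soil-moisture bucket.  Growth ceases once DVS has reached 2, but
    cohorts keep ageing and dying.
    """
    teff = max(0.0, 0.5 * (weather.tmax + weather.tmin) - params.tbase)
    tt = state.tt + teff
    dvs = dvs_update(tt, params)

    lai_g = state.lai_green
    if state.dvs < 2.0:
        gross = (
            params.lue
            * weather.radiation
            * (1.0 - math.exp(-params.k_ext * lai_g))
            * stress.f_water
            * stress.f_nutrient
        )
    else:
        gross = 0.0

    fr = _interp(params.frtb, dvs)
    d_root = fr * gross * params.cvr
    above = (1.0 - fr) * gross
    d_leaf = _interp(params.fltb, dvs) * above * params.cvl
    d_stem = _interp(params.fstb, dvs) * above * params.cvs
    d_storage = _interp(params.fotb, dvs) * above * params.cvo

    # cohort ageing in SPAN units (days at 35 °C), then death past SPAN
    ages = state.cohort_age + teff / (35.0 - params.tbase)
    alive = ages <= params.span
    dead_lai = float(state.cohort_lai[~alive].sum())
    new_age = ages[alive]
    new_lai = state.cohort_lai[alive]
    if d_leaf > 0.0:
        new_age = np.append(new_age, 0.0)
        new_lai = np.append(new_lai, params.sla * d_leaf)

    dead_mass = dead_lai / params.sla if params.sla > 0 else 0.0
    w_leaf = max(0.0, state.w_leaf + d_leaf - dead_mass)

    et = params.et_demand * stress.f_water
    sm = state.sm + (weather.precip - et) / (1000.0 * params.rdmcr)
    sm = min(params.sm0, max(0.0, sm))

    return CropState(
        doy=weather.doy,
        tt=tt,
        dvs=dvs,
        cohort_age=new_age,
        cohort_lai=new_lai,
        lai_brown=state.lai_brown + dead_lai,
        w_leaf=w_leaf,
        w_stem=state.w_stem + d_stem,
        w_storage=state.w_storage + d_storage,
        w_root=state.w_root + d_root,
        w_leaf_dead=state.w_leaf_dead + dead_mass,
        sm=sm,
        cum_converted=state.cum_converted + d_root + d_leaf + d_stem + d_storage,
    )


def initial_state(params: CropParams, start_doy: int, lai0: float = 0.1) -> CropState:
    """Emergence state: one seedling leaf cohort, soil at field capacity."""
    if lai0 < 0:
        raise InputError("initial LAI must be non-negative")
    if lai0 > 0:
        ages = np.array([0.0])
        lais = np.array([lai0])
    else:
        ages = np.empty(0)
        lais = np.empty(0)
    return CropState(
        doy=start_doy,
        tt=0.0,
        dvs=0.0,
        cohort_age=ages,
        cohort_lai=lais,
        lai_brown=0.0,
        w_leaf=lai0 / params.sla if params.sla > 0 else 0.0,
        w_stem=0.0,
        w_storage=0.0,
        w_root=0.0,
        w_leaf_dead=0.0,
        sm=params.smfcf,
        cum_converted=0.0,
    )


@dataclass
class SimResult:
    """Season simulation output: one state per weather day."""

    states: list[CropState]

    @property
    def lai(self) -> np.ndarray:
        return np.array([s.lai_green for s in self.states])

    @property
    def lai_brown(self) -> np.ndarray:
        return np.array([s.lai_brown for s in self.states])

    @property
    def doys(self) -> np.ndarray:
        return np.array([s.doy for s in self.states])

    @property
    def dvs(self) -> np.ndarray:
        return np.array([s.dvs for s in self.states])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "doy": self.doys,
                "dvs": self.dvs,
                "lai_green": self.lai,
                "lai_brown": self.lai_brown,
                "w_leaf": [s.w_leaf for s in self.states],
                "w_stem": [s.w_stem for s in self.states],
                "w_storage": [s.w_storage for s in self.states],
                "w_root": [s.w_root for s in self.states],
                "sm": [s.sm for s in self.states],
            }
        )


def simulate_season(
    params: CropParams,
    weather: Sequence[WeatherDay],
    san: SanRecord | None = None,
    init: CropState | None = None,
) -> SimResult:
    """Deterministic day loop over the weather series.

    Returns one state per weather day; the trajectory has exactly the
    length of the weather series.
    """
    weather = list(weather)
    if not weather:
        raise InputError("weather series is empty")
    state = init if init is not None else initial_state(params, weather[0].doy)
    states: list[CropState] = []
    for wday in weather:
        stress = stress_factors(state.sm, san, params)
        state = advance_day(state, wday, stress, params)
        states.append(state)
    return SimResult(states=states)


def rescale_lai(state: CropState, new_lai: float) -> CropState:
    """Return a copy of ``state`` whose green LAI equals ``new_lai``.

    Live cohort contributions are scaled uniformly (ages untouched) and the
    live leaf mass pool with them, so an externally analysed LAI can be
    pushed back into the mechanistic state.  From a zero-LAI state a single
    fresh cohort is created.
    """
    if new_lai < 0:
        raise InputError("LAI must be non-negative")
    lai_g = state.lai_green
    if lai_g == new_lai:
        return state
    if lai_g == 0.0:
        sla = 0.0022  # only reachable for a dead canopy; fresh cohort, nominal SLA
        return replace(
            state,
            cohort_age=np.array([0.0]),
            cohort_lai=np.array([new_lai]),
            w_leaf=new_lai / sla,
        )
    factor = new_lai / lai_g
    if new_lai == 0.0:
        return replace(state, cohort_age=np.empty(0), cohort_lai=np.empty(0), w_leaf=0.0)
    return replace(
        state,
        cohort_lai=state.cohort_lai * factor,
        w_leaf=state.w_leaf * factor,
    )


def ensemble_mean_state(states: Iterable[CropState]) -> CropState:
    """Member-mean state of an ensemble sharing one phenology.

    Ensemble members advanced under identical weather share thermal time,
    DVS and cohort age structure; only LAI-linked quantities differ.  The
    mean state averages cohort contributions, pools and soil moisture.
    """
    states = list(states)
    if not states:
        raise InputError("empty ensemble")
    ref = states[0]
    n_coh = {len(s.cohort_lai) for s in states}
    if len(n_coh) != 1:
        raise InputError("members have different cohort structures")
    mean_lai = np.mean([s.cohort_lai for s in states], axis=0) if len(ref.cohort_lai) else ref.cohort_lai
    return replace(
        ref,
        cohort_lai=np.asarray(mean_lai),
        lai_brown=float(np.mean([s.lai_brown for s in states])),
        w_leaf=float(np.mean([s.w_leaf for s in states])),
        w_stem=float(np.mean([s.w_stem for s in states])),
        w_storage=float(np.mean([s.w_storage for s in states])),
        w_root=float(np.mean([s.w_root for s in states])),
        w_leaf_dead=float(np.mean([s.w_leaf_dead for s in states])),
        sm=float(np.mean([s.sm for s in states])),
        cum_converted=float(np.mean([s.cum_converted for s in states])),
    )
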