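# Methods

This note documents the models, the defaults and the design choices
behind `maizelai`, in the order data flows through the package.

## Crop model

The simulator (`maizelai.crop`) is a deliberately reduced daily process
model that keeps the parameter semantics of the WOFOST core set that is
sensitive to LAI, while replacing the full photosynthesis scheme with a
light-use-efficiency growth equation. It exists because the estimation
methods (ensemble filtering, the hybrid switch, per-date calibration
with averaging) are defined over *any* daily LAI process model; a small
transparent surrogate makes them testable end to end.

**Phenology.** Development stage DVS is piecewise linear in accumulated
effective temperature: `DVS = tt/TSUM1` to anthesis, then
`1 + (tt−TSUM1)/TSUM2`, clamped at 2 (maturity). Daily effective
temperature is `max(0, (Tmax+Tmin)/2 − Tbase)` with `Tbase = 8 °C`.
Defaults `TSUM1 = 890`, `TSUM2 = 710 °C·d` are the calibrated
spring-maize values. The first day with DVS ≥ 1 is therefore exactly the
first day the thermal sum reaches TSUM1 — an invariant the tests assert.

**Growth.** Daily gross assimilate is
`G = LUE · R_g · (1 − exp(−k·LAI)) · f_water · f_nutrient` (kg DM/ha),
with global radiation `R_g` in MJ m⁻² d⁻¹, extinction `k = 0.6` and
`LUE = 12.5 kg ha⁻¹ (MJ m⁻²)⁻¹`. A root share `FRTB(DVS)` is converted
by `CVR`; the rest is split by `FLTB/FSTB/FOTB(DVS)` and converted by
`CVL/CVS/CVO`. Partition tables are DVS-knot/value pairs with linear
interpolation; the above-ground fractions sum to 1 at every knot (a
constructor invariant). The knots make the leaf fraction fall steeply
after anthesis (0.18 at DVS 1, 0.12 at DVS 1.4, 0 at maturity) with the
storage-organ fraction rising to 0.69 at DVS 1.4 — the behaviour of
maize partitioning around grain fill.

**Senescence.** Leaf area lives in cohorts. Each day's leaf growth adds
a cohort of `SLA·ΔW_leaf` (SLA = 0.0022 ha/kg); cohorts age by
`Teff/(35 − Tbase)` per day, implementing the SPAN convention ("days at
35 °C", default 28), and die past SPAN. Green LAI is exactly the live
cohort total; dead area accumulates as brown LAI (no litter fall — a
known simplification that slightly overstates the late-season brown
signal). Growth ceases at DVS = 2 but cohorts keep dying.

**Stress.** Water stress ramps linearly over soil moisture between
wilting point SMW and field capacity SMFCF (defaults 0.20/0.46 cm³/cm³);
a one-layer bucket of depth RDMCR = 2.4 m receives rain and loses
`ET_demand·f_water` (3.5 mm/d). Nutrient limitation is the Liebig
minimum of saturating responses `x/(x+h)` of available N, P, K with
half-saturations `h = 100/9 mg/kg`, chosen so a reference content of
100 mg/kg gives a factor of 0.9. This is a documented surrogate for an
explicit soil nutrient balance; soil available nutrients are direct
inputs per quadrat.

**Mass balance.** Pools plus dead leaf mass minus the seedling mass
equal cumulative converted assimilate to 1e-9 relative (asserted).

**LAI rescaling.** To push an analysed LAI back into the mechanistic
state, all live cohort contributions (and the live leaf mass pool) are
scaled uniformly, ages untouched; a dead canopy revives as one fresh
cohort. This keeps the age structure of the canopy consistent with the
filter's corrections.

The surrogate constants (LUE, SLA, k, Tbase, ET demand, emergence LAI
0.1) were fixed once so the default season peaks at green LAI ≈ 3.5–5
around mid-August and senesces to ≈ 1–1.5 by season end — the seasonal
shape of spring maize in a cold-temperate monsoon climate. They are
package configuration, not calibration products.

## Synthetic scenes

`maizelai.synthetic` emulates the study conditions: a season from
emergence (day-of-year 152) for 140 days; sinusoidal seasonal
temperature (mean 12 °C, amplitude 10.5 °C, warmest around doy 200,
day-to-day noise 1.8 °C), radiation 16 ± 7 MJ m⁻² d⁻¹, and
gamma-distributed rain on 35% of days. Soil available N/P/K are uniform
over the field spans (N 40–410, P 10–80, K 20–340 mg/kg), which drives
between-quadrat LAI heterogeneity. Three field campaigns (doys 181, 210,
237 — 30 June, 29 July, 25 August) observe ~30 quadrats with additive
Gaussian noise (sd 0.2 m²/m², truncated at 0); six reflectance surveys
(doys 165–237) sample the canopy.

Reflectance is Beer–Lambert soil/leaf mixing per band:
`ρ_b = ρ_soil,b + (ρ_mix,b − ρ_soil,b)(1 − e^{−k_b·LAI_total})`, with
`ρ_mix` the green/brown asymptote mixture weighted by LAI fractions and
per-band noise sd 0.01. Defaults (e.g. soil red 0.12, green-leaf red
0.05, green-leaf NIR 0.45, brown-leaf NIR 0.25) reproduce the two
qualitative behaviours that matter: NDVI from noise-free reflectance is
strictly increasing but strictly concave in green LAI (saturation), and
at fixed total LAI more brown leaf lowers NIR and raises red (the
senescence shift). What the generator does **not** emulate: radiative
transfer geometry, atmospheric or view-angle effects, spatially
correlated soil, cloud gaps in the survey schedule. Passing tests on
these scenes therefore demonstrate the estimators' behaviour under the
stated mechanisms, not their field accuracy.

All randomness flows from one seed through named `SeedSequence`
substreams (weather, soils, per-quadrat observation streams), so scenes
are bit-reproducible.

## Index models

The five indices use the standard formulas on the 490/550/680/720/800 nm
bands; MTVI2 uses the form with `5·√RED` inside its square-root
discriminant. Regression is LAI-on-VI by ordinary least squares (so the
fitted line can be applied directly to index maps); selection is by
largest |R| with ties broken in the listing order NDVI, RVI, OSAVI,
EVI2, MTVI2. Significance classes use the two-sided t test
`t = r·√((n−2)/(1−r²))`: `**` for p < 0.01, `*` for p < 0.05. Negative
LAI predictions are clamped to 0 (physical bound) with a logged count;
pixels with undefined indices are masked.

## Ensemble filter

State vector: green LAI only, with an identity observation operator —
the minimal choice consistent with LAI observations. Defaults: 50
members; initial ensemble by multiplicative lognormal perturbation (sd
10%) of the initial LAI; process noise additive Gaussian with sd 5% of
each member's LAI; observation ensembles perturb the observation with sd
10% of its value (floor 0.05 m²/m²). Covariances use the `N−1` divisor.
Member LAI is floored at 0 after every perturbation and update, and the
mechanistic state is rebuilt by the cohort rescaling above.

**Divergence guard.** On each update day (observations are daily after
temporal IDW) one uniform(0,1) draw `R` forms
`E = R·N_day·σ₁²/(D·σ₂²)`, where `D` is the window length, `N_day` the
current day index, and σ₁²/σ₂² are the variances of the observed and the
forecast-mean LAI series over days 1..N_day. The gain is multiplied by
`E` only when σ₁²/σ₂² > 4 *strictly* and `E ≥ 1`; a vanished σ₂² skips
the guard with a warning. After inflation the scalar gain is clipped so
`K·H ≤ 1` — a stability choice (prevents overshooting past the
observation) that is flagged in the gain log. The gain log records, per
update day: gain, both ensemble covariances, σ₁², σ₂², E, the draw, and
whether inflation was applied.

## Calibration

Free parameters (default set: SMFCF, SMW, SM0, RDMCR, SPAN; any
parameter may be freed) are optimised one campaign date at a time by
bounded Nelder–Mead, minimising the squared error between simulated and
observed plot-mean LAI on that date, with a budget of 200 objective
evaluations per date split across one restart from the incumbent. The
final value of each free parameter is the arithmetic mean of the
per-date optima. Per-date starting points are shared (the supplied
initial parameter set); convergence tolerances are `xatol 1e-6`,
`fatol 1e-12`. Bound-pinned optima and exhausted budgets are flagged,
not hidden. With noise-free self-generated observations and one free
parameter the scheme recovers the generating value essentially exactly
(the objective has a root per date).

## Pipeline and stages

Stage boundaries come from campaign midpoints with an inclusive-date
convention: the early stage ends at `floor((c1+c2)/2)` and the late
stage starts at `ceil((c2+c3)/2)`, so the default campaigns give 14 July
(doy 195) as the last early day and 12 August (doy 224) as the first
late day; a half-day midpoint falls in the mid stage from both sides.

Remote-sensing LAI per survey date uses the per-campaign model nearest
in time; daily series come from inverse-distance weighting in time with
power 2 (exact pass-through on survey days; beyond the last survey the
series tends to the nearest value). Assimilation runs from season start
(the mid-stage output before the first survey is the assimilation
trajectory). The hybrid switch is the first day the analysis-mean state
reaches DVS = 1 — deterministic given weather, since phenology does not
depend on LAI — with the calendar late-start day as fallback; from the
switch the ensemble is collapsed to its member-mean state and the model
free-runs with no further updates. The free-run tail is bit-identical to
running the daily recursion from the switch state (asserted). Per-day
labels `vi | assimilation | hybrid` follow the calendar stages, and one
seed governs every stochastic part of a run.

## Evaluation conventions

R² is computed from the fitted line (L independent, observations
dependent) over the observation variance; RMSE from the raw estimates.
The pair is deliberately asymmetric: a constant offset keeps R² = 1 but
appears fully in RMSE. For the stated least-squares fit this R² equals
the squared Pearson correlation (asserted to 1e-10), and so is bounded
by 1. CV uses the sample SD (n−1), consistent with the ensemble
covariance convention.

## Experiment problem sizes

The packaged experiments use scaled problem sizes chosen for quick,
single-CPU reproduction: the Kalman-oracle comparison runs 1000 members
for 30 steps; the divergence experiment 100 days with 20 members and the
model's light-use efficiency cut to 12% (a stalled forecast against a
growing truth); the combined-season comparison 30 quadrats, 30 members
and 140 days, with the estimators' model biased to 85% light-use
efficiency. These sizes are defaults of the experiment functions and can
be raised.

## Known limitations

- The growth equation has no source/sink photosynthesis, no CO₂ or
  photoperiod response, and a single-layer water bucket; it reproduces
  seasonal LAI shape, not yield physiology.
- Brown LAI never falls (no litter drop), so the late-season brown
  fraction is an upper bound.
- The filter state is scalar LAI; biomass pools are adjusted only
  through the proportional rescaling, not estimated.
- The guard's σ₁²/σ₂² uses temporal series variances, so it needs a few
  update days of history before it can fire.
- Synthetic-scene realism is qualitative; none of the numeric accuracies
  measured on it transfer to field data.
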