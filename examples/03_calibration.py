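"""Calibrate a crop parameter against per-date plot LAI and average.

Observed plot-mean LAI on the three campaign dates is generated by the
simulator itself at TSUM1 = 890 degC d; the optimiser then starts from a
wrong value and must find it back, once per date, and the per-date optima
are averaged.
"""

from dataclasses import replace

from maizelai import CropParams, gen_weather, simulate_season
from maizelai.calibration import CalibrationSpec, calibrate_mean

weather = gen_weather(140, seed=3)
params_true = CropParams()
sim = simulate_season(params_true, weather)
doys = list(sim.doys)
campaigns = (181, 210, 237)
observed = tuple(float(sim.lai[doys.index(d)]) for d in campaigns)
print("observed plot LAI:", ", ".join(f"doy {d}: {o:.2f}" for d, o in zip(campaigns, observed)))

spec = CalibrationSpec(
    free_parameters={"tsum1": (700.0, 1100.0)},
    campaign_doys=campaigns,
    observed_lai=observed,
)
result = calibrate_mean(spec, replace(params_true, tsum1=780.0), weather)
print("per-date TSUM1 optima:", [round(d["tsum1"], 1) for d in result.per_date])
print(f"averaged TSUM1: {result.params.tsum1:.1f} degC d (generating value "
      f"{params_true.tsum1:.0f})")
# With noise-free observations every per-date optimum lands on the
# generating value, so the average recovers it exactly.
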