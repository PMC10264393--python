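# dragontherm

A thermal-ecology analysis pipeline for the Canberra grassland earless
dragon (*Tympanocryptis lineata*), a small heat-sensitive agamid whose
above-ground activity is squeezed from both ends of the temperature range:
cold mornings delay emergence, and hot middays force retreat into burrows.
The package turns temperature-sensitive radio-telemetry and microclimate
logger series into a per-day **energetic cost** statistic and hindcasts it
over a multi-decade daily-maximum temperature record.

It is written for thermal and behavioural ecologists who have (or want to
simulate) three kinds of data: transmitter pulse-rate telemetry, replicate
microhabitat temperature loggers (open sun, shaded ground, burrow), and
flow-through respirometry measurements of resting metabolic rate (RMR).

## The analysis in brief

1. **Calibration** — per-transmitter quadratic pulse→temperature curves and
   linear cross-scale calibrations (e.g. T_body = 1.063·T_trans − 3.20).
2. **Telemetry processing** — pulse averaging over each 90-s listening
   window to one temperature per 10-min slot; daylight windowing by NOAA
   solar geometry; day-quality filters (≥10 h span, no ≥120-min gap);
   matching each reading to the microhabitat whose temperature it most
   closely resembles.
3. **Activity classification** — a dragon is *inactive* when its
   transmitter sits below shaded-ground temperature for ≥2 consecutive
   slots (cool refuge) or varies by <0.5 °C (or shows a flat signal) over
   ≥3 slots (stationary); *active* when it exceeds both shade and burrow
   temperature. Daily activity is summarised with Wilson binomial
   intervals and modelled as a quadratic in daily maximum air temperature.
4. **Energetics** — a random-intercept mixed model
   log RMR = a + b·log T (natural logs, T in °C; published fit
   RMR = e^(−11.7 + 2.99·log T) ml O₂ g⁻¹ h⁻¹) evaluated hourly on
   transmitter temperatures; the energetic cost of a day is
   mean hourly RMR / proportion of daylight hours active — the energy an
   animal must recoup per active hour.
5. **Hindcast** — the fitted activity quadratic and cost LOESS applied
   day-by-day to a DJF daily-Tmax record; yearly means expressed as
   anomalies/ratios against the 1960–1990 baseline and smoothed with a
   span-0.3 LOESS.

A `synthetic_data` module generates all four input streams with known
ground truth — including a rule-following shuttling lizard agent — so the
entire pipeline is testable end-to-end without field data.

## Worked example

```python
import dragontherm as dth
from dragontherm.synthetic import ClimateScenario, gen_climate

# simulate and analyse a tracking campaign: 3 dragons x 30 days spanning
# cool-to-hot daily maxima, plus a 12-individual respirometry arm
res = dth.run_field_campaign(seed=5)
m = res.activity_model
print(f"activity optimum: {m.vertex:.1f} C (R2 = {m.r2:.2f}, n = {m.n_days} days)")
print(f"fitted RMR model: log RMR = {res.rmr_model.a:.2f} + {res.rmr_model.b:.2f} log T")

# hindcast over an 80-year record with +3 C summer warming after 2000
scenario = ClimateScenario(start_year=1941, end_year=2020, base_summer_mean=27.5,
                           daily_sd=4.0, trend_start_year=2001, trend_magnitude=3.0)
summer = dth.summer_subset(gen_climate(scenario, seed=0))
yearly = dth.project_yearly(summer, m, res.cost_curve)
late = yearly[yearly["year"] >= 2001]
print(f"post-2000 Tmax anomaly: {late['tmax_anomaly'].mean():+.1f} C")
print(f"post-2000 activity ratio: {late['activity_ratio'].mean():.2f}")
print(f"post-2000 cost ratio: {late['cost_ratio'].mean():.2f}")
```

prints

```
activity optimum: 23.6 C (R2 = 0.92, n = 30 days)
fitted RMR model: log RMR = -11.97 + 3.08 log T
post-2000 Tmax anomaly: +3.1 C
post-2000 activity ratio: 0.89
post-2000 cost ratio: 1.47
```

Read: the simulated dragons are most active on ~24 °C days; a +3 °C
post-2000 summer depresses yearly activity by ~11% while the energy that
must be recouped per active hour rises by ~47% — the cost response is much
larger than the activity response because hot days combine higher resting
metabolism with fewer active hours.

The same stages are available as a CLI for file-based workflows:

```sh
dragontherm simulate --config config.yaml --out data/
dragontherm classify --config config.yaml --telemetry data/telemetry.csv \
    --microclimate data/microclimate.csv --out slots.csv
dragontherm fit-rmr --config config.yaml --rmr data/rmr.csv --out rmr_model.yaml
dragontherm cost --config config.yaml --slots slots.csv --rmr-model rmr_model.yaml \
    --tmax tmax.csv --out days.csv --models-out models/
dragontherm hindcast --config config.yaml --climate data/climate.csv \
    --activity-model models/activity_model.yaml --cost-curve models/cost_curve.yaml \
    --out yearly.csv
```

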