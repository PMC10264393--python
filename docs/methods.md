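# Methods

This note documents the models, rules, and numerical choices implemented in
`dragontherm`, and what the synthetic-data generators do and do not emulate.

## Temperature scales and calibration

Transmitter pulse rate maps to temperature through a per-transmitter
least-squares quadratic (each unit has its own thermistor curve). The fit
requires ≥4 calibration pairs spanning ≥10 °C and must be strictly monotone
over the calibrated pulse range; a sign change in the derivative is treated
as corrupted calibration data and rejected. Pre- vs post-deployment drift
is screened by comparing predicted temperature at the shared pulse-range
midpoint; the default flag threshold of 0.5 °C is a screening choice, not a
measured constant.

Cross-scale relations (transmitter → skin, body, and ambient-logger
temperature) are ordinary unweighted least squares. Transmitter
temperatures track skin temperature closely, so the pipeline treats
T_trans as the skin-scale quantity; correcting it through the body or skin
line is exposed as an optional step and is off by default.

## Solar geometry

Sunrise and sunset use the NOAA solar-position equations (Fourier
expansions of the equation of time and declination) at the conventional
zenith of 90.833°, which folds in refraction and the solar radius. The
routine agrees with the NOAA reference calculator to within ~2 min and
with R `geosphere::daylength` to within 0.01 h. Note that the
astronomical mean day length over 1 Oct–28 Feb at Canberra is 13.82 h;
figures near 13.5 h sometimes quoted for this season appear to be rounded.
Polar latitudes (|lat| ≥ 66.5°) are out of scope. Timestamps are stored as
naive UTC and converted through a fixed per-site offset (+11 h for
Canberra daylight-saving summers) so results never depend on the host's
timezone database.

## Telemetry processing

The receiver listens for 90 s at the head of each 10-min slot; all pulses
in that window (one suffices — dawn part-windows included) are averaged to
a single slot value. Days are then filtered: records outside
sunrise–sunset are dropped (nocturnal signals are unreliable), dragon-days
whose daylight records span <10 h are dropped, and dragon-days containing
a run of ≥12 consecutive missing slots (120 min) on the slot grid between
their first and last daylight record are dropped. Gaps are measured on the
slot grid, not wall clock, and only interior dropouts count — a
late-starting morning is the span rule's business. This keeps the span
rule monotone: adding records can never get a retained day dropped by it.

Each slot is matched to the microhabitat (sun / shade / burrow) whose
temperature is closest to the transmitter's; ties resolve in the fixed
order burrow → shade → sun, preferring the buffered habitat. Replicate
loggers (≥3 per microhabitat) are averaged at read time; under-replicated
site-slots are still averaged but flagged. Band summaries use left-closed
5 °C bands labelled by midpoint and 1 °C (floor) histogram bins.

## Activity classification

Two passes over each dragon-day, runs resetting at slot gaps:

1. **Inactive runs** — (a) ≥2 consecutive slots with T_trans below shaded
   ground temperature (cool refuge); (b) any 3-slot window whose T_trans
   range is <0.5 °C *or* whose signal-strength range is below the
   stationarity threshold (default 2 receiver units — the field rule gives
   no number). The temperature and signal conditions combine as OR,
   mirroring the "temperature or signal" phrasing of the field rule.
2. **Active** — remaining slots with T_trans above both shade and burrow
   temperature. Slots satisfying neither rule inherit the previous slot's
   state; the first slot of a day defaults to inactive, since dragons
   emerge well after sunrise.

Run rules take precedence over the instantaneous open-habitat rule: an
animal sitting still in the open is resting, not foraging, and observed
midday stationary periods support runs dominating. Daily activity is the
active fraction of classified daylight slots; hour-of-day proportions are
pooled within 5 °C daily-Tmax bands with Wilson score intervals (the
closed form; it inverts the score test exactly, which the tests verify by
root-finding). The activity–Tmax relationship is an unweighted quadratic
OLS (a dragons-per-day weighted variant sits behind a flag). Predictions
clamp the input to the fitted Tmax range and the output to
[activity_floor, 1]; the floor (default 0.05) keeps the cost ratio finite
where the fitted parabola approaches zero outside the data.

## Energetics

log RMR = a + b·log T with natural logs and T in °C. At the published
coefficients (a = −11.7, b = 2.99) this gives 0.216 ml O₂ g⁻¹ h⁻¹ at
30 °C — physiologically plausible, where a base-10 reading would be
orders of magnitude off; natural log is therefore the implemented
convention. The model is fitted by REML as a linear mixed model with a
random intercept per individual (repeat measurements); a sex term is
assessed in a companion fixed-effects fit and only its p-value is kept.
Degenerate inputs (a single individual, or numerically zero residual
variance, where REML is undefined) fall back to OLS with a warning.
Predictions clamp temperature to the measured 20–38 °C chamber range.

Daily mean RMR evaluates the curve on each local clock hour's mean
transmitter temperature and averages over hours; hours with no slots are
skipped and partial hours contribute what they have. Hourly evaluation
matters: the curve is convex, so averaging hourly RMRs is not the same as
evaluating the daily mean temperature. Energetic cost is
mean RMR / max(prop_active, activity_floor), flagged when the floor
engages.

## LOESS

Classical LOESS: tricube weights over the span-fraction nearest
neighbours, local polynomial of degree 1 or 2, evaluated on a 200-point
grid with linear interpolation between knots and boundary clamping
outside. Degree-d LOESS reproduces global degree-d polynomials exactly,
which the tests use as an oracle; degree 1 cross-checks against
statsmodels lowess. Defaults: degree 2 with span 0.75 for the
cost-vs-Tmax and RMR-vs-Tmax curves (no span is prescribed for these) and
span 0.3 for yearly smoothing (prescribed). Duplicate-x degeneracies fall
back to the local weighted mean.

## Hindcast

Summer is December–January–February. Days are assigned to their own
calendar year (Dec 1975 belongs to 1975) — the most literal reading of a
per-year DJF mean; an austral-season option (December joins the following
January/February) sits behind a flag since the convention is genuinely
ambiguous. Yearly means of daily predicted activity and cost are divided
by the mean over the 1960–1990 baseline years, so baseline ratios average
to exactly 1 by construction. Tmax values beyond the fitted ranges (recent
records reach 44 °C, beyond field data) are clamped to the range boundary
before prediction — no extrapolation of the quadratic or the LOESS.
Missing Tmax days are skipped; a year with <50 % of its summer days
present is flagged low-coverage. As a derived diagnostic, days whose
predicted active time (activity proportion × astronomical day length)
falls below 7 h are counted per year — a published population-risk
threshold for lizard activity restriction.

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate:

- **Microclimate** — shade follows a sinusoid peaking at 14:00 local
  (peak = day's air Tmax + 8 °C, overnight minimum = Tmax − 16 °C); sun
  adds a daylight-only excess peaking 17 °C above shade (so ~25 °C above
  air Tmax, matching copper-pipe loggers that average 59 °C maxima on hot
  days); the burrow is an exponentially smoothed (τ = 8 h), lagged
  transform of shade clipped to the observed 12–36.5 °C envelope. Three
  replicate loggers per habitat with 0.3 °C scatter.
- **Lizard agent** — overnight it rests in a warm refuge (burrow + 2 °C;
  the overnight refuge temperature is unmeasured, so this offset is a free
  parameter); it emerges 1.5 h after sunrise and retreats 0.5 h before
  sunset; by day it basks in full sun while that stays below the panting
  threshold (40.6 °C skin) minus a 3 °C margin, shuttles around its 35 °C
  set-point when full sun would overheat it, and enters the burrow when
  even shade comes within the margin of the threshold or when sun is too
  cool (<28 °C operative) to make foraging worthwhile. The transmitter
  relaxes toward the occupied microhabitat temperature with τ = 2 min
  (within the few-minute lag such transmitters show) plus N(0, 0.3²)
  sensor noise. Active slots carry a deterministic upward ±0.4 °C
  positional zigzag and an alternating ±4-unit signal strength; inactive
  slots a constant signal. This behavioural variation is part of the
  policy: a basking animal at solar noon would otherwise be
  indistinguishable from a stationary one under the <0.5 °C rule. The
  set-point and margin are choices (the laboratory work gives limits, not
  preferences). Active slots always sit ≥0.5 °C above both shade and
  burrow by construction, so the open-habitat rule holds on the ground
  truth.
- **Respirometry** — log VO₂ = a + b·log T + u_i + ε with per-individual
  intercepts u_i ~ N(0, σ_id²); 12 individuals, alternating sexes,
  chamber temperatures {20, 25, 30, 35, 38} °C.
- **Climate** — daily Tmax = seasonal cosine (peaking mid-January,
  centred so the zero-noise DJF mean equals the configured 27.5 °C) +
  N(0, 4²) daily noise + a step or ramp trend from a configurable start
  year. Each calendar date maps to a fixed phase (Feb 29 shares Feb 28's)
  so zero-noise years repeat exactly; a `leap_days=False` option drops
  Feb 29 for exact-invariance tests.

What the generators do **not** emulate: radiative/convective heat-budget
physics, weather fronts and autocorrelated heat waves, multi-animal
interactions, transmitter signal propagation, or nocturnal data loss.
Passing tests therefore demonstrate that the pipeline's rules and models
recover known structure under the stated statistical assumptions — not
that those assumptions exhaust real field data.

## Problem sizes and defaults

The bundled campaign simulates 3 dragons × 30 days with daily maxima
evenly spanning 12–44 °C (identification of both curve tails), a
12-individual respirometry arm (σ_id = 0.1, σ_resid = 0.1 on the log
scale), and 80-year climate records; parameter-recovery checks use 200
seeded replicates. These sizes identify every fitted quantity while
keeping any single analysis in seconds.

## Known limitations

- The agent's activity curve peaks near 24 °C with a plateau through the
  low 30s rather than a textbook parabola; the quadratic is a deliberately
  simple summary (as in the field analysis), and its R² here (~0.9)
  reflects the smoother synthetic world, not field scatter.
- Daylight accounting only: nocturnal metabolism and active (field)
  metabolic multipliers are out of scope, making the cost statistic a
  conservative floor.
- The hindcast treats the activity and cost curves as stationary across
  decades — no acclimation, phenology shifts, or habitat change.
- Microclimate noise is white; real logger series are autocorrelated.
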