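# Methods

This note documents the modelling choices behind `heatrisk`: what each
stage assumes, which parameters matter and why their defaults were chosen,
what the synthetic generator does and does not emulate, and the known
limitations.

## Heat Index computation

The two-stage NWS procedure is implemented exactly, in double precision,
with no rounding before categorization. Two details deserve comment.

*Stage-1 convention.* Published statements of the simplified Steadman
formula differ in whether its output already **is** the preliminary
estimate (the canonical NWS reading, where the formula's constants perform
the averaging) or whether it is to be **averaged with the air
temperature**. Both conventions appear in operational descriptions, and
the difference matters only in a narrow band around the 80 °F branch
point. The package implements both behind `steadman_mode={"paper","nws"}`
and defaults to the averaging variant. The branch decision is made on the
preliminary value at exactly ≥ 80 °F.

*Adjustment windows.* The dry-air correction applies for RH < 13 % and
80 °F ≤ T ≤ 112 °F and is subtracted; the humid correction applies for
RH > 85 % and 80 °F ≤ T ≤ 87 °F and is added. Strict inequalities on the
humidity conditions and inclusive bounds on temperature follow the
operational statement; boundary cases (e.g. RH = 13 %, T = 87 °F) are
pinned by unit tests. Risk bins are lower-inclusive, upper-exclusive, so
every finite HI maps to exactly one category even at the printed shared
endpoints (32 °C is Extreme Caution, 41 °C is Danger).

## Quality control

QC is purely descriptive. Calendar dates are parsed strictly (February 30
is an error, never a coerced NaT); continuity is checked against the full
3-hourly grid between the first and last observation; outliers are flagged
with the 1.5·IQR rule using linear interpolation between order statistics
(the most common quantile convention, documented so flags are
reproducible) but never removed — extremes in station records are
ordinarily genuine weather. Flagging is per variable. Gaps are a hard
failure in the pipeline: lagged features are undefined across gaps, and
silently imputing them would blur the leakage guarantees. Min-max scaling
is fitted on the training partition only and applied unchanged elsewhere;
out-of-range values extrapolate beyond [0, 1] by design. Scaling applies
only to the machine-learning models; the state-space models receive raw
values.

## Feature construction and evaluation protocol

Features per 3-hourly timestamp: temperature (°C), relative humidity (%),
hour, day of month, month, four one-hot season indicators (winter =
Dec–Feb, spring = Mar–May, summer = Jun–Aug, autumn = Sep–Nov — standard
meteorological quarters, configurable), and HI lagged 1, 3 and 6 steps
(3, 9, 18 hours). Rows without full lag history are dropped. The split is
chronological; in the decade configuration training covers 2014–2021 and
testing 2022–2023.

Evaluation is one-step-ahead and conditional: the tree models read the
observed lag features of each test row, and the state-space adapters run
the Kalman filter over the test block with parameters frozen at their
training estimates, so both model families use exactly the information the
persistence benchmark uses. MASE therefore compares like with like: the
model's test MAE scaled by the in-sample mean absolute one-step naive
error (m = 1 on the 3-hourly grid — the benchmark is the previous
*observation*, not the previous day).

Cross-validation is expanding-window: the training span is cut into
`folds + 1` contiguous blocks; fold *k* validates on block *k + 1* after
fitting on all earlier blocks, so training sets strictly grow and no fold
sees its own future. Grid search minimises mean CV RMSE with ties broken
by declaration order and never touches the test partition.

## Model registry and defaults

- **naive** — persistence, no parameters.
- **arimax** — SARIMAX(2,0,2) with exogenous temperature, humidity and the
  four season indicators (which sum to one and double as the intercept).
- **sarimax** — SARIMAX(1,0,1)(1,0,1)₈; s = 8 matches the daily cycle at
  3-hourly resolution.
- **rfr** — random forest, 300 trees, unrestricted depth, square-root
  feature subsampling. Per-tree predictions are exposed (leaf-value lookup
  via `tree_.apply`, identical to each tree's `predict`), and the ensemble
  point prediction is their arithmetic mean, so the interval construction
  below is exactly consistent with the point forecast.
- **gboost** — XGBoost, 500 rounds, learning rate 0.05, early stopping
  (50 rounds) on the chronologically last tenth of the training block.

Orders and ensemble sizes are editorial defaults of this package — large
enough to be stable, small enough to fit in minutes on one CPU — and all
are overridable per run. Adapters for a given spec and seed are fully
deterministic. Non-convergence of the state-space optimiser is recorded on
the adapter (`converged`) rather than raised: the filtered predictions
remain usable and the diagnostics make the condition visible.

Within-fold constant feature columns (e.g. `month` inside a short CV
block) carry no information and pass through the adapters' internal scaler
unscaled rather than raising; the user-facing `MinMaxScaler` keeps the
strict constant-column error.

## Scenario projection

Future temperature and humidity are the historical per-calendar-month
means, expanded as constants within each month (no synthetic diurnal
cycle; an explicit design choice — the optional historical mean diurnal
anomaly is not added by default). Scenario shifts are deterministic
(−0.5 °C / −2 pp, 0 / 0, +1.0 °C / +3 pp); noise is independent Gaussian
per timestep with level-dependent SDs of 0.5/1.0/1.5 °C for temperature
and 2/4/6 pp for humidity (low/moderate/elevated — ordered magnitudes
spanning typical intra-month dispersion; the levels are conventions of
this package). Humidity is clipped to [0, 100] after shift and noise.
Noise is drawn once per scenario seed, so every model sees the same
scenario weather.

Projection is recursive: at step *t* the lag-*k* feature is the prediction
made at step *t − k*, seeded by the last six observed HI values. Interval
bounds at each step are the 2.5th/97.5th percentiles (linear interpolation
of order statistics) of the per-tree predictions at that step; they are a
forest-only feature — other models project point trajectories. These
bands quantify conditional model dispersion under the assumed predictors,
not full climate uncertainty: the scenario inputs themselves are treated
as given.

## The synthetic generator

The generator emulates the *structure* of a monsoon-megacity synoptic
record: a gap-free 3-hourly grid; an annual temperature harmonic with an
optional phase-locked first overtone (a negative overtone flattens the hot
season into the characteristic April–October plateau while keeping winter
short and sharp); an early-afternoon diurnal harmonic; AR(1) weather noise
started from its stationary law; and relative humidity built from a
baseline, an optional monsoon harmonic, a negative coupling to the
de-seasonalized temperature anomaly (hot afternoons are dry even though
hot months are humid), and white noise, clipped to [5, 100] % — the 5 %
floor keeps the dry-air HI correction reachable without physically absurd
values. A closed-form expression for the implied T–RH correlation follows
from the variance decomposition and is exact up to clipping.

The Dhaka-like preset solves the annual-cycle coefficients from three
anchor conditions (summer mean 29.5 °C, winter mean 20.7 °C, April mean
28.4 °C) as a linear system evaluated on the actual grid, and fixes the
remaining parameters (diurnal amplitude 3.2 °C, AR(0.75) with innovation
SD 1.2 °C, RH baseline 81 %, monsoon harmonic 7 pp, coupling −5.2 pp/°C,
RH noise 5.5 pp) so that the overall T–RH correlation, the
Danger-and-above share and the monthly risk-band structure resemble the
published description of the 2014–2023 Dhaka record.

What the stand-in does **not** emulate: observation rounding and
instrument error; weather regimes and fronts (noise is a single AR(1)
process with constant variance); year-to-year trend; the exact monthly
profile (a two-harmonic cycle cannot place every month — its March is
~1 °C cooler than Dhaka's); and any dependence structure beyond the
stated couplings. Consequences worth knowing: because HI here is an
*exact* smooth function of features present in the matrix, boosting can
interpolate it almost perfectly and outperforms the forest on this data,
and the forest's tree dispersion (hence interval width, ≈ 5 °C) reflects
feature-subsampling variance rather than irreducible noise. Tests passing
on this stand-in demonstrate correctness of the pipeline's mechanics and
realistic relative behaviour, not agreement with any particular real
station's absolute numbers — projected scenario means, for instance, sit
≈ 1 °C above those published for the real Dhaka record because the
stand-in's hot-season climatology is slightly warmer-humid than the real
one.

## Numerical and degenerate-input conventions

- All HI arithmetic in float64; °C↔°F round-trips are inverse to ~1e−9.
- Percentiles everywhere use linear interpolation of order statistics.
- MAPE is reported in percent and suppressed (with a warning) when the
  target contains zeros; MASE raises on constant targets (zero
  denominator).
- Durbin–Watson raises on all-zero residuals; Breusch–Pagan raises on
  rank-deficient regressor sets and uses the fitted values as the default
  auxiliary regressor in the pipeline.
- Seeds: one master seed per run; each component derives a stable 31-bit
  seed from SHA-256 of `"{master}:{label}"`, so adding a component never
  shifts another component's stream.

## Known limitations

- No missing-data handling beyond detection: the pipeline requires the
  complete grid (the forward-fill escape hatch is deliberately absent from
  the default path).
- Recurrent neural estimators are out of scope; the registry is the
  extension point.
- Scenario projections are stationary climatological what-ifs, not
  forecasts: no trend extrapolation, no climate-model forcings, no
  cross-scenario blending.
- Interval calibration is assessed on conditional one-step test
  predictions; recursive multi-year bands inherit model dispersion only
  and should be read qualitatively.
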