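# Methods

`wearbp` models the dependence of home-measured blood pressure (BP) on
lifestyle factors recorded by a wrist wearable, one subject at a time, and
converts the fitted model into a short list of actionable lifestyle
recommendations. This note documents the model, the numerical choices, and
what the synthetic validation does and does not demonstrate.

## Data model

Three per-subject streams:

* **wearable minutes** — heart rate (beats/min), steps (count/min),
  walking/running speed (km/h, present only while moving), floors climbed;
  channels may drop out independently;
* **sleep sessions** — staged intervals (light / REM / deep), which the
  package groups into whole-night periods when gaps are ≤ 60 min;
* **BP readings** — systolic/diastolic pairs (mmHg), nominally twice a day
  (morning and evening), in practice irregular, sometimes missing and
  sometimes duplicated within one sitting.

Timestamps are ISO-8601 with explicit offsets on disk and timezone-naive
(UTC clock) in memory. Duplicate wearable timestamps keep the last record
(a later sync overwrites a partial one). Readings within a 2-hour session
are collapsed (mean of values and of times, by default).

## Feature engineering

For each reading at time *t* and prediction horizon *h* ∈ {0, 12, 24, 48}
hours, windows end at *e = t − h* and features summarize the half-open
intervals (*e* − w, *e*] for w ∈ {24, 48, 72} h:

* `steps_w`, `floors_w`, and the three active-level minute counts are raw
  sums for w = 24 and **average daily totals** for w = 48, 72, keeping all
  three windows on the same physical scale;
* `heart_rate_w`, `speed_w` are means over minutes carrying the channel;
  `maxHR_w` is the window maximum; `heart_rate_1` is the 1-hour mean;
* per-minute activity levels come from steps and heart-rate zones with
  HRmax = 220 − age and zone bounds at 0.5/0.7/1.0 × HRmax (upper bound
  inclusive; a minute with < 10 steps or zone-1 HR is sedentary, zone 2 is
  lightly active, zone 3 very active; missing HR counts as sedentary);
* sleep duration features (total and per stage) are clipped-to-window
  session overlaps, daily-averaged for 48/72 h; `bed_time_w` / `up_time_w`
  come from the main (longest) sleep per night ending in the window,
  averaged over nights; `slpHR_w` is the mean HR over in-sleep minutes;
* `measure_time` is the reading's clock time in decimal hours.

Bedtime uses a shifted clock (12:00 → 36:00) so 23:30 and 00:30 are
numerically adjacent and a tree split never straddles midnight
artificially. Wake time stays on the standard clock.

**Coverage and missingness.** A window summary is missing when fewer than
50% (HR, speed) or 25% (steps, floors, active minutes) of the window's
minutes carry the channel; these thresholds are configuration. A reading is
dropped entirely only when its 24-h window falls below the 25% step
coverage — so the first day of wear survives at horizon 0 but not at
horizon 24, where its shifted window predates the stream. Remaining missing
cells are median-imputed; during cross-validation the medians come from the
training fold only, and the pre-imputation mask is retained.

## ARIMA one-step-forecast features

BP history carries predictive signal of its own. Because readings are
irregular, each target series is first resampled onto a regular grid
(default 12 h, two points per day) anchored at the first reading, by linear
interpolation between the bracketing readings, never extrapolating.
An exhaustive search over orders (p, d, q) ≤ (3, 2, 3) — crossed with
seasonal (P, D, Q) ≤ (1, 1, 1) at the one-day period when enabled — fits
every candidate with statsmodels' SARIMAX (constant included when
d + D = 0) and keeps the lowest AICc; candidates are visited simplest
first, so criterion ties resolve to fewer parameters, and failed fits are
skipped. The winning model's one-step-ahead prediction, conditioned only on
grid points **strictly before** each reading, is attached as `SBP_arima` /
`DBP_arima`. The strict look-back matters: interpolated grid values after a
reading depend on that reading, so conditioning on them would leak the
target. The driftless random walk (0, 1, 0) is forecast by its closed form
(last value) rather than through the Kalman filter, whose diffuse
initialization only approximates it. A constant series short-circuits to a
(0, 1, 0) fit with zero innovation variance.

## Random forest and Shapley-value selection

The regressor is a 500-tree random forest with per-split candidate fraction
0.33 and minimum split size 2, seeded and single-threaded for
reproducibility. The selection pipeline is: fit on all features → rank by
mean absolute Shapley value over training samples → keep the top
`ceil(0.5 · K)` (ratio configurable) → refit on the kept features. The kept
set is returned in canonical feature order so a ratio of 1.0 reproduces the
original model exactly.

Shapley values are computed **exactly** under marginal (interventional)
expectations over a background sample. For one tree, one explained row x
and one background row z, each leaf partitions its distinct path features
into a set N that x satisfies and z does not (must be in the coalition),
a set D that z satisfies and x does not (must be out), and dead features
neither satisfies (leaf unreachable). The leaf's coalition game is an
indicator times the leaf value, whose Shapley values have the closed form
+v/(n·C(n+d, n)) for members of N and −v/(d·C(n+d, d)) for members of D.
Summing over leaves, trees and background rows gives attributions that are
identical to brute-force enumeration of all 2^K feature subsets (verified
in tests to 1e-10) and satisfy efficiency — baseline + Σφ equals the
prediction — to float accuracy. Inputs are rounded through float32 before
the path comparisons because sklearn casts to float32 at predict time;
without this, a sample can land on the wrong side of a threshold.

The accumulation kernel is numba-compiled and deduplicates explained and
background rows that share a pass/fail bit pattern at a leaf. Defaults of
64 background rows and up to 128 explained rows per model keep a full
500-tree attribution under ~4 s on one CPU; both are configuration, and the
`shap_importance` cap when explaining everything is 200 background rows.
Rankings are insensitive to these sizes well before those defaults.

Alternative importance scores for comparison: absolute Pearson correlation;
information gain (mutual information after 10-quantile binning of feature
and target — the binning recipe is ours, the method reference gives none);
and the forest's mean decrease in impurity.

## Evaluation

Metrics: MAE, RMSE, MAPE and R². MAPE is the aggregate form
n·MAE / Σ|BP| × 100 — a ratio of totals, not a mean of per-sample
percentage errors. R² is the standard 1 − SSE/SST.

`cross_validate` runs repeated k-fold CV (default 5 × 5) with random,
non-chronological splits; folds are resampled per repeat. Imputation,
ARIMA fitting and SHAP selection happen inside each training fold; the
ARIMA spec fitted per fold is shared between the ARIMA-as-model and
ARIMA-as-feature routes. `compare_models` shares fold assignments across
models so the paired Student's t-test on per-sample absolute errors is
valid; a zero-variance, nonzero-mean difference vector is flagged as
degenerate instead of fabricating a p-value. k = n with one repeat reduces
to leave-one-out. Ablation ladder: SimpleMean (training-mean predictor),
ARIMA (one-step forecast used directly), RF (lifestyle features only),
RF-ARIMA (adds forecast features), RFSV (adds selection).

## Recommendations

Only factors a subject can deliberately change are eligible: measurement
time, all heart-rate summaries (`heart_rate_*`, `maxHR_*`, `slpHR_*`) and
the BP-history forecasts are excluded even when they rank first. Window
variants collapse to a base factor (steps_24/48/72 → steps) whose
importance is the **maximum** over its windows — summing would triple-count
one factor. Direction comes from the Pearson correlation between a
feature's values and its per-sample Shapley values: r ≤ −0.2 → "increase"
(higher values lower predicted BP), r ≥ +0.2 → "decrease", otherwise
"regularize". The ±0.2 threshold is configuration; a numeric rule was
needed where visual inspection of attribution plots is the usual practice.
The report attaches the period BP summary (mean/min/max), weekly
first-vs-last statistics of daily means, and the OLS trend slope in
mmHg/day. Mapping (factor, direction) pairs to clinical wording is left to
configuration templates; the package does not generate medical advice text.

## Synthetic cohorts and what they show

The generator emulates the study's measurement regime: minute-level
circadian heart rate with activity coupling, Poisson-seeded walking bouts
(speed per bout, HR raised into zones 2–3 proportionally), a day-level step
budget with relative SD 0.35 around 7 000 steps, nightly sleep around 23:00
± 0.7 h for 7.3 ± 0.6 h in 90-minute light/deep/light/REM cycles, BP
readings at ~08:30 and ~19:30 with 20-min jitter, configurable missingness
and per-minute wearable dropout, and 90 days per subject — matching a
twice-daily, three-month protocol (≤ 180 readings).

BP is generated as base + Σ coefficient · z(feature) + AR(1) residual,
where z standardizes the **realized** feature (recomputed with the same
window rules the features module applies) by fixed analytic constants, not
sample statistics — so ground truth is sample-independent, and with zero
noise an OLS fit recovers the planted coefficients to machine precision.
The AR(1) innovation SD is the profile's `noise_sd` (AR = 0 gives i.i.d.
noise). The default planted effects are steps_24 (−5 mmHg/SD), bed_time_24
(+4) and heart_rate_1 (+4, deliberately non-actionable); noise_sd defaults
to 4 mmHg. Cohorts derive per-subject seeds deterministically and can
jitter coefficients to create inter-individual heterogeneity.

Passing tests on these cohorts show the pipeline recovers known planted
structure under realistic sampling, missingness and noise. They do not show
clinical validity: real BP has medication, diet, sodium, stress and
seasonal drivers the generator omits; real wearable channels have
device-specific artifacts; and real effects are neither linear nor
stationary. Feature scales other than the directly planted ones
(e.g. the analytic mean of windowed heart rate) are approximations, which
shifts intercepts but not recovery of signs or rankings.

## Problem sizes used in validation

The acceptance checks run at the study conditions (90 days, 180 readings,
500 trees, selection ratio 0.5, noise 4 mmHg): 20 seeds for planted-effect
recovery and for the selection cost/benefit (single 75/25 held-out split
per seed), 10 seeds for the RF-ARIMA ablation on 45-day subjects with
AR = 0.8, 25 random tiny forests (≤ 8 features, ≤ 5 trees, depth ≤ 3) for
brute-force Shapley equivalence, and reduced ARIMA order bounds
(p, q ≤ 1–2, d ≤ 1, non-seasonal) inside cross-validation. The
`scripts/acceptance.py` runner recomputes the same quantities at 8–10 seeds.

## Known limitations

* Exact interventional SHAP is O(trees × leaves × explained × background ×
  path); very deep forests on thousands of rows need smaller background or
  explained subsets (both exposed).
* The exhaustive SARIMA search at full default bounds fits ~400 candidates
  per series; cross-validation uses reduced bounds by default.
* Random CV splits follow the stated protocol but let temporal
  autocorrelation inflate apparent accuracy when AR dynamics are strong;
  `cross_validate(..., chronological=True)` uses contiguous time blocks
  instead and is the stricter choice for strongly autocorrelated targets.
* Trees with more than 64 distinct features on one root-to-leaf path are
  rejected (bitmask width); unreachable at the feature counts used here.
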