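# Methods

## The prediction problem

A tomato truss carries a handful of flowers that open over ~1–2 weeks.
Once a flower's anthesis date is known, fruit development is driven
almost entirely by temperature: the fruit is harvest-ready when the
integrated temperature (thermal time) since anthesis reaches a
cultivar-specific total, here 1100–1200 °C·days. The pipeline
therefore needs three measurements: *when each flower bloomed*, *how
many flowers became retained fruits*, and *the daily mean temperature
between bloom and harvest* — the last partly forecast, because the
prediction is wanted weeks before the harvest.

## Detection evaluation

Predictions are matched to ground-truth boxes per class, greedily by
descending IoU with ties broken by higher confidence then input order,
at IoU threshold 0.5 (a prediction matching an unclaimed ground truth
at ≥ 0.5 is a true positive). Greedy matching is the standard
VOC-style evaluation; on random instances it coincides with the
maximum-assignment oracle our tests enumerate exhaustively, and the
test suite asserts that agreement on 200 instances per run. AP uses
all-point interpolation (precision monotonized from the right) over an
exhaustive sweep of the distinct confidence cutoffs; mAP is the
unweighted mean over classes. When a denominator is zero (a class with
no predictions or no ground truths) the metric is defined as 0 so that
empty classes cannot poison aggregate reports.

## Tracking

Identity is purely positional: each active track claims its nearest
current-frame box by Euclidean center distance, greedily by increasing
distance (ties by lower ID), within a gate defaulting to 25 % of the
frame width. Unclaimed boxes spawn new tracks with the next position
number; positions are never reused. Before matching, an optional
global-translation compensation subtracts the median displacement of
mutual-nearest track/box pairs, which absorbs camera shifts caused by
greenhouse work without any appearance model.

State machine: `flower → fruit` requires `fruit_confirm_frames = 3`
consecutive fruit-class matches (single-frame misclassification
tolerance), with the fruit-set date backdated to the first frame of
the confirming streak; a flower unseen 14 days becomes `non_fruiting`;
a fruit unseen 3 days becomes `dropped`. The class transition is
applied at match time (inside assignment) rather than in a separate
pass, so a single frame update leaves the state machine consistent;
the horizon rules run after each frame. `completed` fruits remain
matchable — they are still visible on the truss — while dropped and
non-fruiting tracks are retired. All horizons are configuration, since
there is no principled universal value; the defaults suit daily to
sub-daily frame cadences.

Diameter is estimated as `mm_per_px × mean(w, h) / 10` cm. The default
scale 0.15 mm/px corresponds to a 65° field of view imaged at 1600 px
from ~17.5 cm; real installs must calibrate. A truss is complete when
every fruit-state track is at or past `min_diameter_cm = 3` and no
flower-state track remains.

## Temperature processing and forecasting

Raw ~5-min logs pass three QC rules before daily averaging: a physical
range gate of [−10, 60] °C, a per-day robust outlier cut at 5 scaled
MADs from the day median, and a minimum coverage of 25 % of the 288
expected records for a day to count as observed. Missing days stay in
the series as masked gaps; nothing is imputed.

The forecaster is an additive model fit by penalized least squares on
observed days:

* **trend** — piecewise linear with 25 evenly spaced candidate
  changepoints over the first 80 % of history; slope changes carry a
  smoothed-L1 (Laplace-prior) penalty with scale
  `changepoint_prior_scale = 0.01`, so the trend is stiff unless the
  data insist. Predictions clip the trend to a floor/capacity of the
  training range ± 5 °C, which is what saturating growth means here: a
  greenhouse's long-run mean cannot wander past its observed envelope.
* **seasonality** — yearly Fourier series with 10 harmonics of the
  365.25-day period. Weekly and daily seasonality are omitted: at
  daily resolution a greenhouse has no weekly cycle worth fitting, and
  the diurnal cycle averages out of daily means by construction.
* **optimization** — L-BFGS-B from a fixed zero/mean initialization
  with analytic gradients; the fit is deterministic and byte-identical
  across runs. `interval_width = 0.95` is carried as metadata only;
  prediction intervals are not produced.

Forecast skill is mean absolute error (MAE), optionally split by
calendar month (greenhouse forecasts are typically better in the
heated winter months than in summer).

## Harvest prediction

The integrated temperature is the inclusive cumulative sum from the
bloom day (day i = 0 contributes). The harvest window for a bloom date
is `[bloom + n_lo, bloom + n_hi]` where `n_lo` is the smallest n whose
inclusive sum reaches the lower threshold and `n_hi` the largest n
whose sum stays at or below the upper one; for constant temperature T
this reduces to `n_lo = ⌈lo/T⌉ − 1`, `n_hi = ⌊hi/T⌋ − 1`. When the
upper threshold is overshot within a single hot day the window
degenerates to the crossing day.

A truss's window is anchored at its earliest bloom date (config:
latest instead), and the representative date used for MAE scoring is
the window midpoint (config: earliest | latest). Temperatures are
measured up to a cutover date and forecast beyond it; interior sensor
gaps are also filled by the model. The lead-time experiment sets the
cutover L weeks before each truss's recorded harvest date,
L ∈ {0, …, 5}, with L = 0 meaning measured temperatures throughout.
Predicted fruit count is the number of tracks in state fruit or
completed — i.e. flowers that set fruit and were not dropped.

With a forecaster of MAE ε over an m-day forecast span, the
accumulated degree-day error is at most ~m·ε, which shifts the
threshold crossing by at most ⌈m·ε / T_min⌉ days (T_min the smallest
daily mean in the window); the end-to-end test asserts this bound plus
the ±2-day quantization introduced by Mon/Wed/Fri harvest
confirmation.

## Synthetic data: what it does and does not emulate

The temperature generator produces a seasonal cosine (annual mean
17 °C, amplitude 7 °C, peak late July — a heated temperate-latitude
greenhouse) plus independent daily weather noise of 2 °C, a
zero-mean diurnal cosine, 0.3 °C per-record sensor noise, out-of-range
spikes at a configurable rate, and outage spans of 2–36 h. The daily
noise level is the scenario's stated condition; it leaves a well-fit
seasonal model with a held-out forecast MAE of ≈ 1.6 °C, i.e. the
skill of a good greenhouse sensor model. Not emulated: multi-day
correlated weather regimes, heating-control setpoint changes, or
sensor drift — so passing tests demonstrate correctness of the
pipeline's arithmetic and robustness to the modeled noise, not skill
on any particular real greenhouse.

The truss generator places flowers on a spaced grid (spacing must
exceed 4× the jitter SD for identifiability), blooms them on given
dates, sets fruit after 7 days, and grows fruit diameter along a
logistic in accumulated degree-days that passes 3 cm at 35 % of the
harvest threshold (no growth curve is universal; only the 3-cm
monitoring endpoint matters downstream). Drop and non-fruiting events
are per-flower Bernoulli draws; camera shifts are global translations
applied from a given date. Default cadence is 1 frame/day (the
tracker's robustness to shifts is exercised explicitly by shift
events rather than by minute-cadence redundancy); tests that measure
per-frame identity preservation raise it to 4/day. Occlusion is not
modeled.

Ground truth records every flower's true ID, event dates, the truss's
true harvest window (computed with the same integration rule on the
true temperatures), and the box→track provenance of every emitted
detection, which is what the identity-preservation metric scores.

The default experiment is seven trusses on one plant, first blooms
10 days apart from 1 September 2020, four flowers per truss 3 days
apart, with a temperature log from September 2018 and forecaster
training on the first two years (through August 2020). These sizes
keep the full pipeline run under a few seconds while giving every
stage non-trivial work.

## Numerical and degenerate-input choices

* Zero-denominator metrics are 0; AP of an empty class warns.
* Equal-distance matching ties break deterministically (lower ID);
  equal-IoU detection ties break by higher score then input order.
* Re-feeding an identical frame is idempotent (no new tracks).
* `daily_average` is invariant to record order; a day below coverage
  is masked, not dropped, keeping the series contiguous.
* The forecaster refuses all-missing series and predictions before the
  training epoch; `harvest_window` reports the partial degree-day sum
  when the series ends before the lower threshold is reached.
* All dates are calendar dates in the greenhouse's local time; date
  arithmetic is in whole days (no DST effects at daily resolution).

## Known limitations

* Tracking is positional only; two objects swapping positions within
  one frame interval would swap identities. The spacing/jitter guard
  in the generator makes this regime explicit.
* The pixel→cm scale is a single global constant per camera; fruit
  depth variation within a truss biases diameter estimates.
* The forecaster has no exogenous inputs (no heating setpoints, no
  outside-weather covariates) and produces no uncertainty intervals.
* Harvest-window attribution of fruit counts is uniform across the
  window by default, a modeling convenience rather than a ripening
  model.
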