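# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind the package. It states no result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The forecasting problem

*Lobesia botrana* is trivoltine at Mediterranean latitudes: three adult
flights per season, monitored with weekly-inspected pheromone delta traps.
The quantity to predict is the **flight peak** — the day of year (DOY) of
maximum male captures for each generation at each monitoring site. Two
predictors are implemented:

1. **Touzeau degree-day baseline** (`lobesia.touzeau`). The Touzeau index is
   the cumulative thermal integral
   `Tou(n) = Σ_{DOY=1..n} max(0, (TM + Tm)/2 − TB)` with base temperature
   `TB = 10 °C` and both daily extremes first clamped to the effective range
   `[0, 30] °C` (sub-zero readings count as 0 °C; accumulation saturates at
   30 °C). Accumulation starts January 1st. Generation g's peak is predicted
   at the first day whose cumulative value reaches the classical milestones
   125 / 500 / 950 °C·day (crossing is inclusive, `≥`; the integral is
   non-decreasing because sub-base days contribute 0, so the crossing day is
   well defined).
2. **Day-level neural classifier** (`lobesia.ml`, `lobesia.nn`). For every
   anchor date in the season, the features of the 14 preceding days are
   flattened into one window (plus the site's longitude and latitude) and a
   feed-forward network with a sigmoid head outputs the probability that the
   anchor date is a flight-peak day. Per-day probabilities are turned into
   at most three peak DOYs by greedy selection of the highest-probability
   days constrained to non-overlapping 28-day spans (ties break to the
   earliest day). The 28-day span width is a package choice: it is wide
   enough that two picks cannot land inside one flight, and narrower than
   the observed spacing between consecutive generations (≈ 40–60 days).

## Weather conditioning

- **Validity rule.** A station-year is usable when it reports on at least
  90 % of the days (`≥ ceil(0.9 · days_in_year)`) and the number of
  sample-deficient days (fewer than `ceil(0.9 · 48) = 44` half-hourly
  records) stays below `max_bad_day_frac · days_in_year`. The default
  `max_bad_day_frac = 0.9` follows the rule as printed in the source
  description of the station network, which is internally odd (it almost
  never rejects); the stricter reading — at most 10 % of days may be
  sample-deficient — is available as `max_bad_day_frac = 0.1`. Both are
  tested; no intent is guessed.
- **Gap filling.** Missing half-hour slots are filled from hourly
  reanalysis-style records: all variables are copied into the :00 and :30
  slots, except precipitation, whose hourly total is halved into each slot.
  This conserves precipitation totals exactly for whole missing hours, a
  property asserted in the acceptance suite. Filled rows are flagged
  `imputed`.
- **Station assignment.** Sites take the nearest *valid* station by
  great-circle (haversine) distance on a WGS-84 mean-radius sphere;
  distance ties break to the lexicographically smaller station id.
  Timestamps are naive local clock time throughout; no DST arithmetic.

## Feature engineering

Per station-day: TM, Tm, precipitation total, mean relative humidity,
accumulated radiation, and mean wind speed per 8-point compass sector
(sector centres at 0°, 45°, …, 315° with ±22.5° half-width; unobserved
sectors are imputed as 0 — calm in that sector — at window-building time).
Cumulative indexes are computed per (kind, start-rule) pair:

- `touzeau` — as above, upper cap 30 °C;
- `gdd` — same form without the upper cap (generic growing degree days);
- `chilling` — cold exposure in the band `(0, 7.2] °C`. At half-hourly
  resolution each qualifying sample counts 0.5 h. At daily resolution the
  day is modelled as a triangle wave between Tm and TM, whose value
  distribution is uniform on [Tm, TM], so chill hours =
  `24 · |(0, 7.2] ∩ [Tm, TM]| / (TM − Tm)` (24 h when TM = Tm inside the
  band). The 7.2 °C threshold is the classic chill-hours convention; the
  chilling formulation in the original study is not restated there, so the
  simplest model consistent with half-hourly data was chosen, with the
  threshold configurable.
- `precip` — accumulated rainfall.

Start rules: January 1st, February 1st, or the **dormancy onset** — the
first day from the autumn equinox (Sep 23) of the previous year whose daily
maximum stays under 10 °C (`metric="tmean"` switches to the daily mean;
a warm autumn falls back to January 1st with a flag). Each series is zero
before its start date and non-decreasing after it; missing days inside the
accumulation range are an error, not silently skipped.

Half-hourly thermal accumulation sums `max(0, clamp(T, 0, 30) − TB)/48` per
sample, which coincides exactly with the daily method on constant-temperature
days (asserted in the acceptance suite).

## The classifier and its search

The network is a dense feed-forward stack with per-layer activations from
{linear, selu, tanh, softmax} and a sigmoid output, trained on binary
cross-entropy with minibatch (256) sgd / adam / rmsprop. Early stopping
monitors validation loss with patience 17 and min_delta 0.17 and restores
the best-epoch weights; the published best four-layer architecture
(96 linear / 336 selu / 64 linear / 144 selu) is packaged as a directly
buildable configuration (`PUBLISHED_BEST_CONFIG`). The default search space follows
the published hyperparameter table: 3–10 layers, intermediate widths
{0} ∪ {32, 48, …, 512} (width 0 = layer absent), last-two widths
{16, …, 464}, learning rates {1e-3, 1e-2, 1e-1}, the three optimizers.

Dataset assembly labels an anchor date positive iff it equals a labeled peak
DOY of its site-season, yielding ~1 positive per 70 negatives; the training
partition is rebalanced to 1:3 (default: random oversampling of positives,
discarding nothing; undersampling of negatives is the desk-scale option).
Splits are by (site, season) group — no group ever spans two partitions —
with canonical sorting before the seeded shuffle so the split is independent
of row order.

Model selection is by **validation peak-matching F1** (τ = 3 days), not
day-level accuracy: day-level log-loss is only the training signal, while
the scientific currency is the peak event. Variable relevance uses
permutation importance: the 14 lag copies of one variable are shuffled
jointly (k = 10 row permutations) and the mean drop in validation peak F1 is
the group's importance.

## Evaluation

Peaks are matched by (site, season, generation) key. A key is a true
positive when both sides carry a DOY within τ days. `F1 = 2PR/(P+R)` with
`P = TP/(TP+FP)`, `R = TP/(TP+FN)`; zero-denominator metrics are defined as
0; true negatives play no role.

The matching window and the treatment of one-sided cells are not fully
specified by the published description, so the package calibrates them
against the published headline scores and makes the calibration transparent:

- default tolerance **τ = 1 day**, and
- default **two-sided** charging: every unmatched event key (pair outside
  tolerance, prediction without observation, observation without
  prediction) counts one FP *and* one FN, making precision and recall
  symmetric in the two event sets (F1 then equals TP / #event-keys).

Under these defaults the packaged 2008–2011 comparison table scores
F1 = 0.017 for the Touzeau column and F1 = 0.626 for the ML column,
matching the published 0.03 / 0.63 pair to within the uncertainty the
unstated matching rule leaves. The alternative one-sided convention
(prediction-only → FP, observation-only → FN) is available via
`unmatched="one-sided"`, and every report is accompanied by an F1-vs-τ
sweep over τ = 0…7 so that no reading is hidden. Under the one-sided rule
at τ = 3 the same table scores 0.040 / 0.776 — the sweep shows the ML column
dominating the Touzeau column at every tolerance, so the qualitative
conclusion is insensitive to the rule.

## Synthetic data

No station records or trap counts are publicly deposited, so the pipeline is
exercised on simulated data (`lobesia.simulate`) that emulates their
structure:

- **Weather**: 48 records/day; temperature = seasonal sinusoid (coldest
  mid-January) + diurnal sinusoid (warmest 15:00) + iid Gaussian noise
  (σ = 1.5 °C); exponential daily rainfall totals on ~15 % of days spread
  over contiguous slot blocks; NW-dominant von Mises wind ("cierzo");
  humidity anticorrelated with temperature; daylight-shaped radiation; on
  ~1 % of days a contiguous run of 2–8 records is dropped entirely
  (missing rows, not NaNs), mimicking short outages. Defaults
  (mean 13 °C, annual amplitude 8 °C) place the 125/500/950 °C·day
  milestones near DOY 127/172/214 — the ranges where the three flights are
  observed in the study area's monitoring network.
- **Captures**: the true process is the same degree-day crossing (base
  10 °C, thresholds 125/500/950); weekly expected counts follow a Gaussian
  kernel (σ = 3 days) around each true peak scaled to a maximum of ~50
  moths/week, drawn Poisson or negative-binomial (variance μ + 0.2 μ²).
  σ = 3 days gives ≈3 weeks of non-zero counts per flight with captures
  trending to zero between generations, as in real weekly trap series; it
  also keeps the weekly-argmax label within one week of the true peak for
  ≥95 % of site-seasons, the premise under which weekly trap inspection can
  date flight peaks at all. Capture magnitudes are free parameters — the
  study reports none.

What the simulator does **not** emulate: spatial autocorrelation between
stations, photoperiod and humidity effects on the insect, trap saturation
and lure aging, multi-year carry-over of population density. Passing tests
on synthetic data therefore demonstrate that the pipeline recovers a known
degree-day process under realistic observation noise — not that the trained
network transfers to field data.

## Flight labeling

Weekly counts are segmented per site-season: a flight starts at the first of
≥2 consecutive positive weeks and ends before the first run of ≥2 zero
weeks (single zero weeks inside a flight do not end it); the earliest three
segments are kept. The peak is the start-of-week DOY of the segment's
maximum count, earliest week on ties — weekly inspection makes intra-week
timing unknowable, so the label is anchored to the week start. The
"trends to zero" run length (2) and the "sustained captures" run length (2)
are configurable; the study quantifies neither.

## Problem sizes and determinism

The shipped experiments use desk scale: the learnability experiment trains
on 50 sites × 4 seasons (≈200 site-season groups, anchors DOY 80–280) with
50 random-search trials over a compact space (2–4 layers, widths ≤ 64),
negatives undersampled to 1:3, max 120 epochs — about one minute on one
CPU. The full-scale space (10,000 trials, full published widths) is reachable
through `SearchSpace` and `n_trials` without code changes. All stochastic
steps — simulation, balancing, splitting, search, training, permutation
importance — are driven by explicit integer seeds and reproduce exactly.

## Known limitations

- The learning-rate grid follows the hyperparameter table's evident intent
  ({1e-3, 1e-2, 1e-1}); its literal arithmetic (10.0 × 10⁻¹ = 1.0) would
  make the largest rate unusable.
- The dormancy rule ("temperature remains under 10 °C") is read as a single
  day's maximum below 10 °C; N-consecutive-day readings would shift
  dormancy-started integrals by days to weeks.
- Predicted generation indexes are positional (earliest crossing/segment =
  generation 1); in a season whose first flight is missed by the traps, the
  labels shift by one generation.
- The evaluator treats each (site, season, generation) slot independently;
  it does not enforce chronological ordering between a season's predicted
  generations beyond what the predictors themselves guarantee.
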