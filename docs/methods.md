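# Methods

This note documents the models, procedures, parameters, and numerical
choices behind `breathprint`, and what the synthetic cohort does and does
not establish about real smart-breathalyzer data.

## Event schema and cleaning

A raw event log is a CSV with one row per user-initiated reading:
`user_id, ts_utc, tz_name, brac, brac_estimate, verified, user_provided,
lat, lon, elevation_m, zip, state, country, note, drink_count, has_photo`
(empty string = missing).  Cleaning applies, in this order:

1. drop rows flagged as not user-provided (e.g. the device was lent out);
2. drop duplicate `(user_id, ts_utc, brac)` triples, keeping the first in
   file order — the duplicate key is a design choice; full-row
   deduplication would differ only when two devices log the same user,
   second and value simultaneously;
3. drop rows with no user id;
4. drop rows whose UTC timestamp cannot be parsed (flagged at parse time,
   removed here so the tally is explicit);
5. drop readings above 0.50 g/dL as physically implausible device errors —
   a reading of exactly 0.50 is retained.

Unverified readings (the user did not confirm the 15-minute wait after the
last drink) are **retained**; verification is a model feature, not an
exclusion.  The `CleaningReport` tallies every rule and must balance
exactly: rows_in − Σ removed = rows_out.  Cleaning is idempotent and, up
to the deterministic duplicate-survivor rule, independent of input row
order.

## The digital phenotype

Every feature for the reading at time *t* uses only (a) the same user's
records strictly before *t* and (b) record-*t* metadata that exists before
the breath sample: the subjective estimate, the timestamp, the location,
and static context tables.  Families:

- **prior BrAC statistics** — mean, min, max, range, median, Q1, Q3, IQR of
  all prior readings.  Quantiles interpolate linearly between order
  statistics; range = max − min.
- **lags** — the last three prior BrAC values.
- **discrimination history** — the previous reading's (estimate − measured)
  and the running mean of prior discriminations.
- **engagement** — days since the first recording, number of prior
  recordings, distinct active days, self-monitoring episodes, and
  cumulative photo/drink-count/note tallies.  A new episode starts at the
  user's first record or whenever the gap to the previous record is
  ≥ 12 h (a gap of exactly 12 h starts a new episode).  Active days use
  the local calendar date when the time zone is known, else the UTC date.
- **temporal** — minutes since the user's last reading (computed from UTC,
  hence available without a time zone), hour of day and day of week from
  local time, US-federal-holiday + New Year's Eve flag (rule-generated for
  any year), and championship-game flags (Super Bowl, World Series, NBA
  finals) with winner-state/loser-state indicators.  The sports table is a
  small factual constant covering the default 2013–2017 calendar window
  and is overridable.
- **geospatial** — haversine distance (sphere radius 6371 km) from the
  previous geolocated reading, distribution statistics of the user's prior
  consecutive-pair distances, the coefficient of dispersion
  (Q3 − Q1)/(Q3 + Q1) (sentinel when the denominator is 0), elevation, and
  counts of distinct prior zips/states/countries.  K-means clustering of
  all coordinates (default k = 120) is provided for density
  visualization; cluster ids are not default model features — a global
  clustering would also break the truncation property the leakage tests
  enforce.
- **free-text notes** — has-note flag and case-insensitive regex counts of
  numeric amounts, container terms, and beverage terms, plus their sum.
- **context** — state tax rates (alcohol, sales, gas, cigarette), poverty,
  heavy-drinking prevalence, urban %, population, and zip-level
  population/urban % joined by key.  Zip codes are join keys only.
- the **subjective estimate** and the **verified** flag enter as features
  of the current record.

After assembly, missing values are replaced by the sentinel −999 — far
outside every natural feature range (BrAC ≤ 0.5, distances and counts
≥ 0) — so boosted trees can use missingness as signal.  The label is
1{BrAC ≥ 0.08 g/dL}, boundary inclusive.

Correlation pruning (`select_features_by_correlation`) greedily removes
the later-listed member of any pair with |Pearson r| above a threshold
(default 0.9), treating the spec order as the a-priori priority, and can
continue down the correlation ranking to a target roster size.  The
default roster has 59 features; the deployed roster is configuration.

## Model and evaluation

`BracClassifier` wraps LightGBM with the study settings: binary objective,
learning rate 0.1, up to 89 trees, L1 = L2 = 0.5, 31 leaves, class weights
n/(2·n_class) (`class_weight="balanced"`), bagging off by default
(fraction 1.0, exposed as configuration), deterministic single-thread
training, and early stopping (patience 5) monitoring validation binary
log-loss — the metric is a design choice; only the patience is fixed by
the protocol.  Users are split 70/10/20 into train/validation/test by a
seeded permutation with largest-remainder rounding; all of a user's
records share one split, so test users are never seen in training.

Evaluation reports ROC-AUC (midrank tie handling), and
accuracy/macro-F1/sensitivity/specificity/precision from the confusion
matrix at the 0.5 probability threshold.  Precision with no positive
predictions is reported as undefined (null), never 0.  The ablation
ladder retrains the same configuration on the same split with: all
features; all but the estimate; all but the prior-BrAC-derived families
(prior statistics, lags, discrimination history); the estimate alone; and
a constant majority-class predictor.  Arm comparisons use a paired
user-level bootstrap of the test AUC difference (users resampled with
replacement, both arms scored on the same resample).

Feature attributions use the boosted ensemble's exact path-dependent
TreeSHAP (`pred_contrib`), which satisfies additivity — base value plus
attributions equals the raw log-odds margin per row (asserted to 1e-6) —
and the null-player axiom (a never-split feature attributes exactly 0).

## Secondary analyses

- **Discrimination vs. mean BrAC.**  Rows need an estimate, verification,
  and a known local time; rows where both the measured and estimated BrAC
  are zero are excluded as device demos.  Per user, mean discrimination is
  regressed on mean measured BrAC (user-level OLS; the reported adjusted
  R² is the user-level one).  A negative coefficient means heavier
  drinkers underestimate more.
- **Learning curve.**  Discrimination is trimmed to the closed central 95%
  of its pooled distribution (the band belongs to the distribution it was
  computed on; re-applying the same band is a no-op), restricted to
  episodes 1–5, averaged as |discrimination| within user-episode, and fit
  with a linear mixed model (random intercept per user, REML; optimizer
  falls back lbfgs → powell → cg on singular steps).  A perfectly constant
  outcome short-circuits to a flat trend rather than a degenerate fit.
- **Ecological regression.**  Per-state mean BrAC, user and record counts;
  death rates regressed on mean BrAC with √users as a covariate using a
  Huber-weighted robust linear model (tuning constant 1.345), normal
  approximation CIs.  The covariate form is chosen over pre-normalizing
  the outcome because the reported quantity is an adjusted coefficient.
- **Hour × day grid.**  7×24 mean-BrAC grid over verified rows with known
  local time (unverified readings inflate means); the count grid uses all
  rows.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions and are not tuned per experiment.

**Engagement.**  Per-user recording counts are log-normal with median 80
and σ = 1.408 (IQR 31–207), capped at 1,500.  Recordings are spread over
active days via a per-user rate r = 1 + lognormal targeting mean 2.69 and
sd 2.21 recordings per active day, active days over a log-normal use
duration (median 106 days, IQR 45–388) placed uniformly in the May 2013 –
June 2017 window, with Fri/Sat/Sun-weighted day selection.  Within a day,
the first reading's hour follows a diurnal propensity grid (evenings
dominant, weekend late nights boosted) and subsequent readings follow at
10–120 minute gaps.  Because the recording-count and rate margins pin the
joint distribution, the realized median of distinct active days comes out
near 34 rather than the ~27 seen in field data; the two margins were
prioritized, and the discrepancy is a known limitation.

**BrAC.**  The latent reading is
z = m₀ + s·u + s·h(dow, hour) + s·loc + e, censored to [0, 0.50] and
rounded to 0.001 g/dL, where u is a right-skewed (centered gamma, shape 2)
user habit deviation with sd 0.042, h peaks at 0.022 g/dL around
weekend midnight–2 a.m., loc adds 0.025 g/dL at one "venue" habit
location per user (of 3, chosen per day), e is AR(1) across consecutive
readings (coefficient 0.5·s), and s is `high_signal_strength`.  Given the
target marginal (mean 0.057, sd 0.065 g/dL), the base m₀ and residual
scale are solved from the censored-normal moment equations, so the
marginal is held fixed while s moves the predictable share of variance;
at s = 0 readings are exchangeable and the classifier's AUC is ~0.5 by
construction.  The implied low:high label ratio at the 0.08 threshold
comes out near 2.3.

**Estimates.**  estimate = measured + intercept_u + slope·(user mean)
− (1 − λ·s)·(measured − user mean) + noise, censored at 0 and rounded to
the app slider granularity (0.005 g/dL).  λ (`estimate_tracking`,
default 0.15) is the within-user tracking of momentary BrAC: people track
their own *typical* level far better than tonight's deviation from it,
which is also why the estimate-only model is the weakest informative arm.
The configured slope (−0.772) and mean discrimination (−0.037 g/dL) are
defined as *realized* quantities after censoring; because censoring at 0
would otherwise shift both, the generator applies small frozen
compensation constants (`_SLOPE_CENSOR_ADJ`, `_INTERCEPT_CENSOR_ADJ`,
`_EPISODE_SHIFT_PER_UNIT`, `_M0_ADJ`, and the rate-distribution
corrections), calibrated once by simulation at the default settings.
`censor_compensation=False` turns them off, giving the literal closed-form
model used by the exact-recovery tests.  Early-episode learning is
planted as an additive pre-clip shift per episode (capped at episode 5)
scaled so the realized slope of mean |discrimination| per episode equals
`episode_improvement` (default −0.002 g/dL/episode) under the analysis's
own trimming and exclusions.

**Missingness and dirt.**  Independently per row: geolocation (and with
it zip/state/country/elevation) absent at 34%, unverified 12%, estimate
absent 25%, notes 0.1%, drink counts 0.87%, photos 1.14%.  Dirt rows are
*added* on top of the clean cohort (so cleaning restores the calibrated
engagement targets): exact duplicates 2%, missing user id 8%,
not-user-provided 14.9%, BrAC > 0.50 at 0.001%, unparseable timestamps
0.1%.

**What the simulator does not model.**  Alcohol pharmacokinetics beyond
per-reading autocorrelation; drift or device recalibration; estimate
entry psychology beyond the linear-bias-plus-tracking form; population
sampling bias in who buys a breathalyzer; and real geography beyond
approximate state centroids with synthetic context tables (the shipped
state table is labelled synthetic and regenerable from a seed).  Passing
tests therefore establish the *pipeline's* correctness and the
recoverability of planted effects under realistic volume, imbalance, and
missingness — not any empirical claim about real cohorts.

**Engagement–consumption coupling.**  Whether heavy users drink more is
not identified by the marginal targets; the generator exposes
`engagement_brac_correlation` (Gaussian-copula rank coupling) and
defaults it to 0.

## Reproducibility and problem sizes

All randomness flows from integer seeds through numpy `default_rng`;
identical configuration + seed reproduces the raw CSV byte-for-byte, and
model training is single-threaded and deterministic.  The test suite uses
cohorts of 60–500 users for unit and distributional checks, 2,000 users
for the ablation-ordering and bias-slope recovery checks, 800 users for
the null-signal control, 100 replicates of 100 users for learning-curve
CI coverage, and 200 replicates of 50 states for the ecological recovery;
`scripts/acceptance.py` runs a 1,500-user cohort end to end.  These sizes
give stable statistics while keeping a full run to a few minutes on one
CPU.
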