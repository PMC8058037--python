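# breathprint

Digital phenotyping of smart-breathalyzer behavior: from raw user-initiated
breath alcohol concentration (BrAC) event logs to a leakage-free behavioral
feature matrix, a class-balanced gradient-boosted classifier of high BrAC,
and the ecological and learning-curve analyses that sit around it.

## The problem

Smart breathalyzers produce event logs of voluntary, user-initiated BrAC
readings: a timestamp, the measured BrAC (g/dL), an optional subjective
"best guess" entered before the breath sample, a verification flag,
geolocation, and sparse annotations (notes, drink counts, photos).  For a
reading taken at time *t* by user *u*, the package asks: **can the
likelihood that the reading is at or above the 0.08 g/dL legal driving
limit be predicted from what was known before the sample was taken?**  The
predictors are the user's own history — prior BrAC trends, lags,
engagement, self-monitoring episodes — plus time-of-week, geospatial
habits, and regional context (state taxes, poverty, heavy-drinking
prevalence, urban/rural mix).

Formally, each reading gets a label y = 1{BrAC ≥ 0.08} and a feature
vector x(t) built **only** from records of the same user strictly before
*t* and from record-*t* metadata available pre-sample (the estimate,
timestamp, location).  A stochastic gradient-boosted classification-tree
model (LightGBM; learning rate 0.1, up to 89 trees, L1 = L2 = 0.5, early
stopping with patience 5, inverse-frequency class weights) is trained on a
70/10/20 user-level split, so test users are never seen in training.
Missing values are encoded as a −999 sentinel so trees can split on
missingness itself.  Around the classifier the package reproduces a
feature-ablation ladder (full model; without the subjective estimate;
without all prior-BrAC-derived features; estimate only; majority class),
exact TreeSHAP feature attributions, "BrAC discrimination" analyses
(estimate − measured, a negative value is an underestimate), and a robust
(Huber) ecological regression of state impaired-driving death rates on
state mean BrAC adjusted for √users.

The proprietary cohort such devices produce is not publicly available, so
the package ships a calibrated synthetic cohort generator
(`breathprint.simulate`) reproducing the engagement, BrAC-marginal,
estimation-bias, diurnal, geospatial, and missingness structure that the
downstream analysis assumes — with a single `high_signal_strength` knob
that scales every predictable channel (at 0, a classifier can do no better
than chance).  See `docs/methods.md` for the generative model and its
calibration.

## Worked example

```python
from breathprint import (SimulationConfig, ModelConfig, generate_cohort,
                         parse_events, clean_events, localize_timestamps,
                         assemble_feature_matrix, split_by_user, run_ablations)
import io

cfg = SimulationConfig(n_users=300, seed=42)
raw = generate_cohort(cfg)                       # raw event log with dirt rows
buf = io.StringIO(); raw.to_csv(buf, index=False); buf.seek(0)
clean, report = clean_events(parse_events(buf))
clean = localize_timestamps(clean)
matrix = assemble_feature_matrix(clean)
split = split_by_user(matrix, seed=1)
result = run_ablations(matrix, split, ModelConfig(seed=1))
print(result.table()[["roc_auc", "sensitivity", "specificity"]].round(3))
```

prints (seed 42/1):

```
                roc_auc  sensitivity  specificity
arm
full              0.837        0.719        0.789
no_estimate       0.812        0.687        0.776
no_prior_brac     0.718        0.524        0.760
estimate_only     0.728        0.500        0.809
majority_class    0.500        0.000        1.000
```

Reading the table: the full digital phenotype separates high from low
readings well (AUC 0.84); dropping the user's subjective estimate costs a
few points (0.81); dropping everything derived from prior BrAC
measurements costs far more (0.72) — the habit history is the workhorse.
The estimate alone is a mediocre predictor, and the constant
majority-class baseline shows the degenerate row (AUC 0.50, sensitivity 0,
specificity 1, precision undefined).

The same flow is scriptable from the shell:

```bash
breathprint simulate --users 300 --seed 42 --out raw.csv
breathprint clean --in raw.csv --out clean.csv --report cleaning.json
breathprint featurize --in clean.csv --out features.csv --manifest manifest.json
breathprint ablate --features features.csv --seed 1
breathprint run --simulate --seed 42 --out run_out/   # full pipeline + report
```

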