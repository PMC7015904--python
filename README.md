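# taskdecomp

Decomposition of time-varying motion data into **task-relevant** and
**task-irrelevant** components when the trial outcome is **categorical** —
e.g. whether a seated thrower delivered a fastball or a breaking ball.

Frameworks such as the uncontrolled manifold require an explicit kinematic
map between joint configurations and a continuous task variable. When the
outcome is a category, no such map exists. `taskdecomp` instead *learns* the
task-relevant direction from the data: a regularized logistic regression is
fitted to predict the trial label from vectorized joint-angle windows, and
the motion data are split along the fitted weight vector.

## Model

Let `X ∈ R^{T×D}` hold one vectorized joint-angle window per trial
(`D = J × F` for `J` joints and an `F`-frame window ending at ball release,
each column z-scored across trials), and `d ∈ {0,1}^T` the trial labels.
The classifier minimizes

```
E(w0, w) = -(1/T) Σ_t [ d_t log f(w0 + X_t w) + (1-d_t) log(1 - f(w0 + X_t w)) ]
           + (λ/2) wᵀw ,        f(z) = 1 / (1 + e^{-z}) ,
```

with λ chosen by stratified 10-fold cross-validation with five repeats.
Given the fitted `w`, the data split in closed form:

```
X_rel = X w wᵀ / |w|² ,      X_irr = X − X_rel ,
```

so `X_rel w = X w` (the task-relevant part carries the entire classification
probability) and `X_irr w = 0` (the task-irrelevant part carries none).
Grouping trials by the predicted class `g ∈ {0,1}` with scalar projections
`s = X w/|w|`, the outcome measures are

* **task-relevant difference** `|m₁ − m₀|` — between-class mean separation,
* **task-relevant variability** `(v₀ + v₁)/2` — average within-class variance,
* **d′** `= |m₁ − m₀| / √((v₀+v₁)/2)` — signal-detection sensitivity.

A "use a similar form" instruction can reduce d′ two ways: by shrinking the
mean separation (*mean modulation*) or inflating the within-class variance
(*variability modulation*). Group-level inference uses paired t-tests across
subjects and a 2×2 within-subject ANOVA (Part × Day) with Tukey post hoc
comparisons.

## Worked example

Two Gaussian trial classes separated by `delta = 4` sd units along a hidden
direction (200 trials per class), fitted and decomposed end to end:

```python
import numpy as np
from taskdecomp import (ScenarioParams, gen_gaussian, fit, cross_validate,
                        decompose, split_by_estimated_class, task_relevant_stats)

params = ScenarioParams(n_per_class=200, n_features=2, delta=4.0, seed=42)
features, labels, truth = gen_gaussian(params)

cv = cross_validate(features, labels, k=10, repeats=5, seed=42)
model = fit(features, labels, lam=cv.chosen_lambda)

parts = decompose(features, model)
groups = split_by_estimated_class(parts, model, features)
stats = task_relevant_stats(groups, model.w)
```

prints (via the accompanying report lines):

```
chosen lambda      : 0.1
held-out accuracy  : 98.00 +/- 0.29 %
held-out AUC       : 0.9976
direction alignment: |cos| = 1.0000
task-relevant difference : 4.018   (planted delta = 4.0)
task-relevant variability: 0.812   (planted sigma_rel^2 = 1.0)
d-prime                  : 4.459
```

The held-out accuracy sits at the Gaussian Bayes rate Φ(2) ≈ 97.7 %, the
fitted direction is aligned with the planted one, and the estimated
difference recovers the planted separation. The variability lands slightly
below the planted within-class variance because grouping by the *predicted*
class truncates each group at the decision boundary; see
`docs/methods.md` for the discussion and for the recovery harness that
isolates this effect.

## Command line

```sh
taskdecomp simulate --scenario baseline --seed 1 --out data/
taskdecomp fit       --input data/trials.csv --out fit/
taskdecomp sweep     --input data/trials.csv --max-frames 20 --out sweep.csv
taskdecomp decompose --input data/trials.csv --model fit/model_S01_day1.json --out dec/
taskdecomp stats     --input data/trials.csv --out cells.csv
taskdecomp report    --cells cells.csv --out report.json
```

All commands accept `--config file.yaml` (sections named after the
commands) and embed the seed plus a config hash in every artifact, so
identical invocations are byte-reproducible.

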