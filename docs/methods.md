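# Methods

## The decomposition

The package targets the situation where per-trial motion recordings (joint
angles over time) come with a categorical outcome label and the map from
motion to outcome is unknown. A linear classifier supplies the missing
map: if a weight vector `w` predicts the outcome from the vectorized
motion window `X_t`, then everything the linear model knows about the
outcome lives in the one-dimensional subspace spanned by `w`. The
orthogonal projector `P = w wᵀ/|w|²` therefore splits every trial into a
task-relevant part `X_rel = X P` and a task-irrelevant part
`X_irr = X (I − P)`, with three exact identities that the test suite
checks on random instances: `X_rel + X_irr = X`, `X_irr w = 0`,
`X_rel w = X w`. Because `P² = P`, `X_rel` is also the unique minimizer of
the squared score discrepancy `|Xw − X_rel w|²` among rank-one-per-row
candidates, and the classification probability is unchanged when `X` is
replaced by `X_rel`.

Any linear classifier could supply `w`; ridge-regularized logistic
regression is used because the outcome model is probabilistic, the ridge
penalty keeps the direction well-defined when `D > T` (119 features from
100 trials is the typical geometry), and the fitted probabilities feed the
predicted-class grouping directly.

The decomposition and all downstream statistics operate on the z-scored
feature matrix used for fitting; an inverse transform back to angle units
is provided for reporting only.

## Classifier and solver

The cost is the mean binary cross-entropy plus `(λ/2) wᵀw`; the bias `w0`
is not penalized (the penalty term is written on `w` alone). The solver is
a damped Newton iteration: full Hessian of the penalized objective,
backtracking (Armijo) line search on the cost, a ridge jitter when the
Hessian is numerically singular, and a plain gradient-descent fallback if
the Newton direction fails to descend. Convergence is declared at gradient
norm ≤ 1e-8 (1e-6 inside cross-validation, where held-out scores are
insensitive to the last digits); `max_iter` defaults to 1000. With `λ = 0`
on linearly separable data the minimum is not attained; this is detected
(all training margins strictly correct) and flagged as non-convergence
with a warning rather than silently returning a diverging iterate.

λ is selected by stratified k-fold cross-validation (k = 10, 5 repeats,
one master seed; every repeat reshuffles the fold assignment) minimizing
the mean held-out cross-entropy; a per-fold z-scoring convention is the
default (training-fold mean/sd applied to the held-out fold). The default
λ grid is data-driven: for a ridge penalty the solution obeys
`|w(λ)| ≤ |∇CE(0)|/λ`, so the top of the grid is set to
`‖∇CE at the null model‖₂ / 1e-3` (weights effectively zero there) and 50
log-spaced values descend four decades from it. Accuracy and AUC (exact
Mann–Whitney normalization via midranks) are reported at the chosen λ;
accuracy s.e.m. is reported on the proportion scale.

The analysis-window length is chosen the same way the classifier is
validated: `frame_window_sweep` evaluates cross-validated accuracy for
F = 1..max_frames windows ending at the release frame and returns the
argmax (ties to the smaller F). With 7 joints and the 17-frame window this
yields the 119-dimensional feature vector used throughout.

### Conventions chosen where the procedure is underdetermined

* **Window anchoring** — the F frames ending at *and including* the
  release frame; exclusive anchoring is available via `include_anchor`.
* **Vectorization order** — joint-major (all frames of joint 1, then
  joint 2, …), frozen and recorded per column in `column_map`; any fixed
  order is mathematically equivalent.
* **Standard deviation** — sample sd (ddof = 1) everywhere, recorded in
  the normalization metadata.
* **Zero-variance columns** — dropped with a logged warning by default
  (they carry no class information and cannot be z-scored); a hard-error
  policy is available.
* **λ selection** — minimum mean held-out cross-entropy (no 1-SE rule).
* **Classification ties** — `p` exactly at the threshold goes to class 0
  and is counted in the log.
* **Angle units** — radians internally; degrees converted on load.

## Preprocessing

Marker trajectories are low-pass filtered with a Butterworth design
applied forward and backward (zero phase). The default is a 12th-order,
10 Hz design at 120 Hz interpreted as the *per-pass* order — the common
reading of "12th-order zero-phase" in biomechanics — with
`order_convention="effective"` available to design at half the order so
the two passes jointly realize it. Edges use reflective padding of 3× the
design order; the residual edge transient this leaves is why the
symmetry-of-impulse test carries a 1e-4 relative tolerance. Ball release
is the first frame whose ball–finger distance *strictly exceeds* the
threshold (default 0.01 m).

## Outcome statistics

All statistics are computed on scalar projections `s = X w/|w|`: every row
of `X_rel` lies on the line spanned by `w`, so scalar and vector
formulations coincide and the unit direction makes them exactly invariant
to rescaling `w`. Per predicted-class group: mean `m_g`, sample variance
`v_g`; difference `|m₁ − m₀|`; variability `(v₀+v₁)/2`; d′ uses the pooled
sd `√((v₀+v₁)/2)` ("common standard deviation of the two distributions").
A zero pooled variance is flagged (`degenerate_variance`) rather than
yielding a silent infinite d′. d′ is reported but not used as a decision
statistic; the difference and variability are tested separately.

Sessions are split into *former*/*latter* halves by trial index (trials
1–50 vs 51–100 under the default 100-trial session; the fraction is
configurable). Group-level inference:

* paired t-tests across subjects (explicit formula, guarded for
  zero-variance differences, cross-checked against `scipy.stats.ttest_rel`);
* a balanced 2×2 within-subject ANOVA (Part × Day) with each effect tested
  against its own effect-by-subject mean square — with two-level factors
  sphericity holds trivially and all sum-of-squares types coincide;
  cross-checked against `statsmodels` AnovaRM;
* Tukey-corrected comparisons among the four cell means using the pooled
  within-subject error term `MS = (SS_{AS}+SS_{BS}+SS_{ABS})/(3(n−1))`
  and the studentized range with `k = 4`, `df = 3(n−1)`. Pairwise
  paired-t tests with a family correction are a reasonable alternative
  convention; the pooled-error Tukey was chosen and is stated here.

Group summaries average per-(subject, day, part) statistics first, then
across subjects.

## Synthetic data

The generator emulates exactly the structure the method assumes: two trial
classes, Gaussian, with means at ±delta/2 along a unit direction `w_true`,
variance `sigma_rel²` along it and isotropic `sigma_irr²` orthogonal to it.
Scenario presets encode the competing hypotheses — `mean_modulation`
multiplies delta by 0.5 with variances unchanged; `variability_modulation`
multiplies `sigma_rel` by 2 with delta unchanged. Defaults: 50 trials per
class per session (one 100-trial session with the two pitch types
alternating within consecutive pairs), delta = 4 and unit sds, placing the
Bayes accuracy at Φ(2) ≈ 97.7 % — the high-but-imperfect regime in which
the method is meant to operate. Symmetric mean placement is the canonical
form; the clouds are isotropic Gaussians within each subspace.

`gen_motion_trials` wraps the same feature distribution into motion-like
trials: smooth per-joint base trajectories (sums of two low-frequency
sinusoids — the exact shape is arbitrary and irrelevant to the method),
the planted feature vector occupying the J×F window before a planted
release frame, and only base-plus-noise outside it, so the window-length
sweep has a discoverable optimum.

What the generator does *not* emulate: temporal autocorrelation of real
joint angles inside the window, non-Gaussian or trial-order-dependent
noise, subject idiosyncrasy in `w_true`, and any nonlinear motion–outcome
relation. Passing recovery tests therefore show the pipeline is correct
and well-calibrated under its own assumptions, not that real throwing data
satisfy them.

### Parameter recovery and the predicted-class truncation bias

`recovery_harness` runs generate → fit → decompose → group → measure over
seeded replicates and reports estimated difference and variability against
the planted delta and `sigma_rel²`, plus `|cos(ŵ, w_true)|`. Grouping uses
the generator's **true** labels by default: the planted parameters are
per-true-class quantities, and grouping by the *predicted* label instead
truncates each group at the decision boundary — within-class variability
is biased downward and the difference upward whenever the classes overlap
(at delta = 2 and unit sd the variability bias reaches ≈ 35 %). The
predicted-class grouping (`split="estimated"`) is retained as an option
and remains the default in the *analysis* pipeline itself, where no ground
truth exists; in the near-separable regime the method targets, the two
groupings coincide for almost every trial. `use_true_w=True` additionally
bypasses the fit, isolating decomposition error from estimation error.

## Problem sizes and tolerances

Simulation-based checks run at sizes where Monte-Carlo error is comfortably
inside the asserted bands: 200 trials/class × 50 replicates for the
modulation-recovery ratios, 500 trials/class for the Bayes-rate and
direction-alignment checks, 8 subjects × 100 replicates for the ANOVA
detection rate, and 1e5 samples for moment-matching. Exact-algebra
invariants use 1e-8…1e-12 tolerances scaled by the data magnitude; the
grid-search oracle refines to 1e-3–1e-4 resolution.

## Known limitations

* Only linear classifiers admit the closed-form split; kernelized or
  deep front ends are out of scope (with a sigmoid first layer the same
  projection applies in principle; with rectified-linear units it does not).
* The task-irrelevant component is reported only through its total
  variance; no dominant-direction statistics are computed in the
  orthogonal complement.
* C3D parsing and inverse kinematics are out of scope: joint angles (or
  pre-extracted marker CSVs) are the expected input.
* p-values from real experiments are not reproducible here because no
  motion dataset is bundled; validation is via synthetic recovery.
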