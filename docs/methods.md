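# Methods

## The fusion model

The Sensor Weighted Network Classifier combines `M × N` binary
one-vs-rest class classifiers into `M` node-level decision rules and one
network-level decision rule.  The node and network levels are not
learned models: they are fixed weighted-voting schemes whose weights are
normalized held-out accuracies.

For a window seen by sensor `m`, classifier `c_mn` emits a binary
accept/reject decision for class `n`.  The decision is encoded as a vote
vector over all classes: an acceptance is the indicator of class `n`; a
rejection votes 1 for every class except `n`.  Under this *complement*
encoding a rejection is informative — it raises every competing class —
and with uniform weights the whole ensemble reduces exactly to plurality
voting over base acceptances (a property the tests verify on random vote
configurations).  An alternative *abstain* encoding, in which a
rejection votes all-zero, is implemented behind the same `vote`
operation and selectable via `FitConfig(vote_encoding="abstain")`; the
complement encoding is the default because it is the only reading under
which rejections let all classifiers collaborate on every decision.

Node scores are `O_mq = Σ_n λ_mn y_nq` with `λ_mn = R̄_mn / Σ_k R̄_mk`,
where `R̄_mn` is the binary accuracy of `c_mn` on held-out data;
network scores are `O_q = Σ_m μ_m O_mq` with `μ_m = R̄_m / Σ_k R̄_k`,
where `R̄_m` is the held-out multiclass accuracy of node `m`.  Both
weight vectors sum to one by construction and all scores lie in [0, 1].
`R̄_mn` is the overall binary accuracy of the accept/reject decision and
`R̄_m` the plain multiclass accuracy of the node — the direct readings
of what each entity outputs.

**Training protocol.**  The training partition is split into three
equally-sampled stratified subsets (per class, shuffled indices are
dealt round-robin into three buckets, so subset sizes differ by at most
one window per class): subset A trains the base classifiers — including
per-(sensor, class) feature selection — subset B provides the accuracies
behind `λ`, subset C those behind `μ`.  A class absent from any subset
raises a stratification error.  A p-fold cross-validation mode
(`weight_mode="cv"`, default `p = 10`) replaces the B/C holdouts with
cross-validated accuracy estimates over the whole training partition;
it is intended for scarce data and is not the default because the
holdout protocol keeps the three estimation roles disjoint.

**Base classifiers.**  k-nearest-neighbour with per-classifier `k`
chosen from the odd grid {1, 3, 5, 7, 9} by stratified cross-validated
binary accuracy (smallest `k` wins ties).  Features are standardized
with training-subset statistics, since kNN is distance-based.  The grid
search performs one neighbour query per fold and derives the
predictions for every `k` from the ordered neighbour table; this is
numerically identical to refitting per `k` (verified against a
brute-force oracle) and roughly five times faster.  The paradigm is
pluggable: anything exposing a `decide(feature_rows) -> bool array`
contract can stand in as a base classifier.

**Tie-breaking.**  Argmax ties (node and network) resolve to the lowest
class index, which makes predictions deterministic.  In floating-point
arithmetic, score ties that would be exact in rational arithmetic can
differ by ~1e-16 depending on accumulation order, so an exact-tie
plurality configuration may resolve to any of the tied classes; tests
treat tied-winner sets accordingly.

## Feature bank and selection

The bank spans time and frequency domains with ~40 features: per axis —
mean, standard deviation, variance, median, min, max, range, RMS, mean
absolute deviation, zero-crossing count about the mean, signal magnitude
area, spectral energy, spectral entropy, dominant frequency (DC
excluded, so gravity does not mask the oscillatory signature) and the
first five FFT magnitudes; across axes — Pearson correlation and
covariance.  The bank is deliberately representative rather than
exhaustive: the contribution under study is the fusion and disturbance
machinery, not a feature catalogue, and the bank only needs to span
both domains and be extensible (any `FeatureBank` with unique names and
total, finite-valued functions can be substituted).

Each classifier `c_mn` receives its own top-`L` list (`L = 10`) ranked
by `|AUC − 0.5|` for the one-vs-rest problem of class `n`, computed by
the Mann-Whitney rank formulation with mid-rank ties.  Scoring distance
from chance rather than raw AUC makes anti-correlated features rank as
informative.  Selection happens on subset A only and is frozen into the
classifier; scoring new data never re-ranks.

## Disturbance models

**Rotational noise.**  The sensing frame is rotated by
`M = Rz(ψ)·Ry(θ)·Rx(φ)` (roll φ, pitch θ, yaw ψ; degrees at every
interface, radians internally, one conversion point).  A biaxial sensor
observes only the first two components of `M·(x_raw, y_raw, 0)ᵀ`, which
collapses to a 2×2 linear map of the raw signals; the map is equivalent
to the full-matrix route to 1e-12 and can only lose energy to the
unobserved third axis, never gain it.  At θ = 90° the x channel becomes
`sin(φ − ψ)·y_raw` — a pure scaled copy of the other axis with all
`x_raw` content lost, the analytically worst case for features that rely
on the static gravity component.  Angles are drawn independently and
uniformly from `[0, ∠_RN]` per axis — the minimal assumption for a level
knob described only as "varied up to a maximum".  Two sampling
granularities exist: per-window (default; arbitrary per-instance
variation) and per-run (one rotation per sensor, emulating a fixed
misplacement).

**Additive noise.**  Zero-mean white Gaussian noise with standard
deviation `σ_AN` in mG, drawn independently per sample and per axis.
The two families are never combined in one disturbance spec; they are
studied separately.

Disturbances are applied to test partitions only — the provenance flags
on `LabeledSignalSet` record every altered window, and the fitting
routine refuses flagged data — reflecting the design-time/runtime
mismatch the study models.

## Synthetic data generator

Each window of activity `a` at placement `p` is
`g(a, p) + s(t) + ε(t)` per axis, where `g` is the projection of unit
gravity onto the two sensed axes, `s` a random-phase harmonic series
(fundamental amplitude, frequency and harmonic count set per activity;
amplitude scaled by the placement's mobility factor, a per-subject
log-normal style multiplier and a per-window jitter draw) and `ε`
white Gaussian floor noise.  The static component is kept unfiltered on
purpose: it is what a rotation visibly corrupts, producing the
standing-vs-lying confusions that make sedentary classes
rotation-sensitive.

Defaults mirror the study design the package targets: 5 placements
(hip, wrist, arm, ankle, thigh — hip and thigh with the lowest mobility
factors), 9 activities (walking, running, cycling, sitting, standing,
lying, stretching, strength training, climbing stairs), 20 subjects,
6-second windows.  The sampling rate (50 Hz), the per-(subject,
activity) window count (4), the noise floor (20 mG, a typical MEMS
accelerometer figure), the subject-style sigma (0.15) and the amplitude
jitter (0.10) are the package's own choices of a realistic desk-scale
configuration; windows per pair and rate trade statistical resolution
against runtime and are plain configuration, not fidelity claims.

What the generator does **not** emulate: biomechanical coupling between
placements, within-window non-stationarity, activity transitions and
segmentation errors (an external segmentation oracle is assumed),
class imbalance, and triaxial or gyroscope channels.  Consequently,
passing robustness properties on this data demonstrates the mechanics
of the fusion — weighting, vote algebra, degradation and dominance
behavior — not field-ready accuracy on real recordings; absolute
accuracy values here are optimistic because the classes are cleanly
separable by construction.

## Evaluation protocol

Per repetition: a fresh stratified 70/30 split, a fit on the clean
training partition, then disturbance and scoring of the test partition
at every grid level.  Fusion experiments redraw the disturbed
`S`-sensor subset per repetition and level.  Curves report mean ±
sample standard deviation (ddof = 1) over repetitions.  Default grids
embed the levels of interest in wider ranges: rotational
{0, 15, 30, 45, 90, 180}° and additive {0, 50, 100, 200, 500} mG; the
default repetition count is 100, with 20 used by the test suite and 10
by the acceptance script as reduced desk-scale profiles.

The `robustness_study` driver fits the full network once per repetition
and derives the single-sensor curves from the fitted nodes: a node is
trained by exactly the procedure a standalone single-sensor fit applies
(per-sensor training is independent, and the subset split depends only
on labels and seed), which the tests assert by comparing the two routes
on the same split.  `run_single_sensor` and `run_fusion` remain the
literal per-experiment entry points.  Within one repetition and level
the same disturbance realization serves the single-sensor curve and all
`S` subsets; realizations are independent across repetitions and
levels.

All randomness flows from a master seed through
`SeedSequence([master, stream, indices...])` with fixed stream ids
(1 = splits, 2 = fits, 3 = disturbances, 4 = sensor subsets), so every
artifact is reproducible bit-for-bit from the master seed and noise
kinds can be recomputed independently without shifting each other's
streams.

## Numerical and edge-case choices

* Rotation matrices are exact trigonometric compositions; orthonormality
  and unit determinant hold to 1e-12 over the full angle range.
* Euler angles are canonicalized into (−180°, 180°].
* Zero disturbance level is an exact no-op (the input arrays are copied,
  never transformed), so level-0 curve points are bit-identical to clean
  runs.
* Constant features standardize with scale 1 instead of 0; correlation
  of a constant axis is defined as 0 so every bank function is total.
* Spectral entropy and dominant frequency of an all-zero spectrum are
  defined as 0.
* Sliding windows discard trailing partial windows; the offset spacing
  is `floor(duration · rate · (1 − overlap))`, clamped to at least 1.
  Default overlap is 0; 50% is a common alternative and is exposed as
  configuration.
* A base classifier with fewer samples of a class than cross-validation
  folds falls back gracefully (fewer folds, or resubstitution accuracy
  in the degenerate single-fold case); fewer samples than the largest
  grid `k` is an error.

## Known limitations

* Accuracy saturates near 1.0 on clean synthetic data, so clean-condition
  comparisons between sensors are less informative than the disturbed
  ones; the interesting regime is under disturbance.
* Additive noise is an admittedly coarse surrogate for displacement; no
  correlated or spike-shaped fault models are included.
* No disturbed-sensor detection or adaptive weight updating: weights are
  frozen at training time by design.
* Evaluation pools all subjects before splitting; no
  leave-one-subject-out protocol is provided.
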