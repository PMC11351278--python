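# Methods

`gazemind` implements a probe-caught thought-classification pipeline for
screen-based eye tracking: gaze streams are segmented into fixations and
saccades with a velocity-threshold (I-VT) filter, global oculomotor
features are computed over the 12 s preceding each experience-sampling
probe, probe ratings are dichotomized into binary labels on nine
dimensions of ongoing thought, and a SMOTE-balanced random forest is
evaluated per participant under stratified 5-fold cross-validation, with
particle-swarm optimization (PSO) selecting the 10-feature subset that
maximizes mean MCC. This note records the model choices, parameter
conventions and known limitations.

## Recording geometry and angular conversion

Gaze is logged as screen proportions at 250 Hz. Proportions are mapped
to pixels linearly per axis; pixel displacements are converted to visual
angle with the exact two-point formula θ = 2·atan(d_cm / 2D), where d_cm
is the on-screen Euclidean separation (px→cm per axis, so non-square
pixels are handled) and D the viewing distance. Defaults describe a
24-inch 16:9 monitor (1920×1080 px, 53.1×29.9 cm) viewed from 60 cm.
Angular feature magnitudes depend on this geometry; it is a required
configuration with documented defaults, not a constant of the method.

## I-VT event detection

Each sample's velocity is the visual angle between the first and last
valid sample within ±10 ms of it, divided by their time separation — a
two-point estimator rather than a regression slope, the simplest reading
of "movement 10 ms before and after". Velocity is undefined for invalid
samples (missing coordinates) and when fewer than two valid samples fall
in the window; such samples are *unclassified*. Defined velocities below
30 °/s are fixation annotations; at or above the threshold, saccade
(the boundary value is a saccade: fixation requires strictly *below*).

Maximal runs of identical annotations become candidate events. Adjacent
same-kind candidates merge only across gaps ≤ `max_merge_gap_ms`
(default 0: only literally successive annotations combine). Candidates
shorter than 60 ms (fixations) or 30 ms (saccades) are relabelled
unclassified rather than absorbed into neighbours, which keeps the
three-way sample partition exact. A sample at time t occupies
[t, t + 1/rate), so event duration is n·4 ms at 250 Hz and abutting
events share boundaries without overlap.

Per event we record duration, centroid, RMS dispersion about the
centroid (fixations), amplitude (visual angle between first and last
valid positions), mean and peak of the defined sample velocities, and
the displacement direction folded to [0°, 90°] from horizontal.

## Trials, labels, screening

A probe labels the 12 s window that precedes it. Events straddling a
window boundary are truncated with duration recomputed (other summaries
are left as computed on the full event; truncation is bookkeeping, not
re-detection). Ratings 1–3 map to the low-end class, 5–7 to the
high-end class, and 4 — or a missing rating — discards the trial for
that dimension only. Only the task question's polarity is canonical
(1–3 = on-task); other dimensions name their 1-end after the first pole
mentioned in the probe question, and the polarity table is data, not
code. Windows whose unclassified fraction exceeds 0.5 (configurable;
no canonical value exists) are screened out, and a participant enters a
dimension's analysis only with ≥ 10 kept trials in each class.

## Features

29 global features per window: fixation duration {count, mean, median,
min, max, range, std, RMSD}, saccade duration {count + the six
statistics}, saccade amplitude and saccade velocity {six statistics
each}, the fixation/saccade count ratio (denominator guarded at 1), and
the horizontal-saccade count (direction within 30° of horizontal,
configurable). Conventions that the feature list leaves open are config
switches with documented defaults:

- *RMSD*: by default the mean per-fixation spatial RMS dispersion (px);
  an alternate mode takes the RMS of fixation durations, since the name
  is filed under duration features in some presentations of this set.
- *Saccade velocity*: per-saccade mean sample velocity by default; peak
  velocity as an alternate, both conventions being common.
- *Amplitude units*: degrees by default, pixels as an alternate.
- Empty event families yield all-zero summaries (the classifier needs
  finite inputs); std is the sample (n−1) deviation, 0 for n ≤ 1.

## Classification

Per participant: stratified 5-fold splits (per-fold class counts within
±1 of proportional), SMOTE applied to the training folds only —
synthetic minority points x_i + u·(x_nn − x_i), u ~ U[0,1), x_nn among
the k = min(5, minority−1) nearest minority neighbours, singleton
minorities duplicated — then a 100-tree random forest (bootstrap
bagging, √29 ≈ 5 features per split, unlimited depth) fit on the
balanced set and evaluated on the untouched, unbalanced test fold.
Scores are tree-vote fractions. Metrics: MCC (0 when any confusion
marginal is empty), rank-based Mann–Whitney AUC with ties at ½,
balanced accuracy, and Cohen's kappa. A test fold missing a class
yields missing metrics, excluded from that participant's fold mean
(stratification makes this rare; silent zeros would bias). The whole
procedure runs 50 iterations with fresh fold splits and fresh SMOTE
draws each time; a dimension's result is the mean/max/min over
iterations of the across-participant mean of fold means.

Seeding: one master seed expands through `numpy.random.SeedSequence`
spawn keys (participant index, iteration, fold), making every sub-run
independently reproducible.

## PSO feature selection

Particles move in [0,1]²⁹ under v' = w·v + c1·r1·(Pbest−y) +
c2·r2·(Gbest−y), y' = y + v', with c1 = c2 = 1.4962, 20 particles and
100 iterations; w = 0.7298 (the constriction-equivalent companion of
those c values; the inertia weight has no canonical printed value) and
velocities clamped to ±0.5 with positions clamped to the box, since
unbounded velocities destabilize rank-based decoding. A position
decodes to the 10 largest components (ties to the lower index), which
enforces the subset size exactly while keeping the update equations in
their standard continuous form. Fitness is the across-participant mean
of fold-mean MCC on the masked features, with fold splits frozen per
search so mask comparisons are paired. Stopping: iteration cap, fitness
= 1, or global best unchanged (|Δ| < 1e-6; float equality needs a
tolerance) for 10 consecutive iterations. pbest/gbest update on strict
improvement, so ties keep the incumbent and the recorded best is
monotone.

By default the selection fitness is the same CV test performance later
reported, which mildly overstates the selected subset's performance (the
subset has seen the test folds through the search). This mirrors the
common wrapper-selection practice the pipeline reproduces; a nested mode
(`nested_selection`) computes fitness on an inner stratified half of
each participant's training data only.

## Synthetic cohorts

The generator emulates what the analysis consumes, not oculomotor
physiology. Scanpaths alternate lognormal-duration fixations (median
250 ms, σ = 0.4 log units) with gamma-amplitude saccades following a
main-sequence peak velocity 75·A^0.6 °/s shaped by a raised-cosine
profile; fixations jitter isotropically (σ = 3 px); missing-data
episodes arrive at 2/min lasting 100–400 ms. Amplitudes are gamma(3,
2°) truncated below 3°, and saccade durations floored at 44 ms: smaller,
faster saccades hold a ±10 ms-smoothed velocity above 30 °/s for less
than the 30 ms minimum and are undetectable *by construction* at 250 Hz,
which would make ground-truth recovery tests meaningless. With these
defaults the detector recovers > 95 % (measured ≈ 99 %) of ground-truth
events within 8 ms (two samples) of their true boundaries.

Cohorts follow the experience-sampling design: 7 participants × 7
sessions × 35 probes at uniform 90–150 s intervals (1,715 probes).
Latent binary states per dimension are independent Bernoulli(0.5);
ratings are drawn from the matching scale end, with a 0.1 chance of the
discarded mid-scale response. Under the null spec gaze is independent
of every state. Under an effect spec, the scanpath parameters inside
the 12 s pre-probe window are scaled according to the latent states.
Effect directions follow the reported class-wise differences (e.g.
longer fixations when off-task, slower saccades when internally
oriented); where a reported pair is not jointly expressible in a fixed
window under a renewal scanpath (more *and* longer fixations), the
duration direction is kept. Magnitudes are small (2–8 % parameter
shifts), calibrated so classification lands in the moderate-MCC regime
(≈ 0.2–0.5) characteristic of probe-caught thought decoding: window-level
feature noise in the generator is far smaller than in real data, so
realistic-looking parameter shifts would otherwise make the classes
nearly separable and every pipeline comparison trivial. A
`windows_only` mode synthesizes gaze only inside pre-probe windows —
the only spans the analysis reads — for cheaper large runs; full-session
synthesis is the default.

A separate feature-level generator plants a signal in an exact feature
subset (Gaussian features, a subset mean-shifted by class). Gaze-derived
features are correlated within families, so only this generator can
state "exactly these 10 features are informative", which the
feature-recovery tests require. Its defaults (0.5–0.6 sd per-feature
shifts, 30–40 trials per class) are chosen so each planted feature
carries *marginal* signal — with large per-feature effects a handful of
features saturates MCC and the rest are not individually necessary, and
no wrapper selector could be expected to find them.

## What passing tests do and do not show

Synthetic cohorts have stationary parameters, independent latent states,
no task structure, no smooth pursuit, no head motion, and noise far
better behaved than real recordings. Green tests certify the pipeline's
mechanics — detection accuracy on known segmentations, metric
identities, leakage guards, chance-level calibration under the null,
signal recovery under planted effects, and the direction of the
PSO-vs-baseline comparison — not performance claims about human data.
Per-dimension MCC values reported for real recordings of this design
cannot be reproduced or validated here, because such recordings are not
publicly available.

## Problem sizes

Default test and acceptance runs use reduced cohorts (3 participants,
~200 kept trials per class for calibration runs; 10 particles and 30
iterations for swarm-recovery runs), sizes at which the measured
quantities' Monte-Carlo error is well inside the asserted tolerances.
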