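# gazemind

Gaze-based classification of the dimensions of ongoing thought.

Probe-caught experience sampling interrupts a person at quasi-random
moments and asks them to rate their current thoughts on several Likert
dimensions (on-task vs. off-task, internally vs. externally oriented,
freely moving, goal-directed, sticky, self- or others-oriented, visual
or auditory). `gazemind` implements the full analysis chain that asks
whether screen-based eye tracking can predict those ratings:

1. **I-VT event detection** — every 250 Hz gaze sample gets an angular
   velocity v from the ±10 ms of surrounding movement; samples with
   v < 30 °/s are fixation, v ≥ 30 °/s saccade, and samples without a
   computable velocity are unclassified. Runs merge into events with
   60 ms / 30 ms minimum durations.
2. **Global oculomotor features** — 29 stimulus-independent statistics
   per 12 s pre-probe window: fixation-duration summaries (count, mean,
   median, min, max, range, SD, RMSD), saccade duration, amplitude and
   velocity summaries, the fixation/saccade ratio and the
   horizontal-saccade count.
3. **Labels** — each rating r ∈ 1..7 is dichotomized (1–3 → low class,
   5–7 → high class, 4 discarded); a participant enters a dimension's
   analysis only with ≥ 10 trials per class.
4. **Classification** — per participant, stratified 5-fold CV; SMOTE
   balances the training folds only; a 100-tree random forest predicts
   the untouched unbalanced test fold; MCC, AUC, balanced accuracy and
   Cohen's κ are averaged over folds, participants and 50 repetitions.
5. **PSO feature selection** — a particle swarm
   (vᵢ′ = w·vᵢ + c₁r₁(Pbestᵢ − yᵢ) + c₂r₂(Gbest − yᵢ), yᵢ′ = yᵢ + vᵢ′;
   c₁ = c₂ = 1.4962, 20 particles, ≤ 100 iterations) searches [0,1]²⁹,
   each position decoding to its top-10 components as a feature subset;
   fitness is the across-participant mean of fold-mean MCC.

Because raw recordings of this kind are rarely shareable, the package
ships a synthetic cohort generator (alternating fixation/saccade
scanpaths with main-sequence saccades, probe schedules, latent thought
states and plantable class effects) so the entire chain is testable end
to end — see `docs/methods.md` for what the generator does and does not
emulate.

## Worked example

Simulate a small cohort with a planted off-task effect (longer
fixations in off-task windows), extract features and classify the
task-relatedness dimension:

```python
import numpy as np
from gazemind import (CohortSpec, CVConfig, DEFAULT_EFFECTS, generate_cohort,
                      build_feature_table, dimension_datasets, run_repeated)

spec = CohortSpec(n_participants=3, n_sessions=4, probes_per_session=20,
                  mid_scale_rate=0.0, seed=2)
effects = {"task_relatedness": DEFAULT_EFFECTS["task_relatedness"]}
cohort = generate_cohort(spec, effects, windows_only=True)
table = build_feature_table(cohort)
datasets = dimension_datasets(table, "task_relatedness")
print("trials per participant:", {p: len(y) for p, (_, y) in datasets.items()})
result = run_repeated(datasets, CVConfig(n_iterations=5, seed=2))
print(result.summary.round(3))
```

```
trials per participant: {'p01': 80, 'p02': 80, 'p03': 80}
        mean    max    min
mcc    0.321  0.383  0.253
auc    0.731  0.750  0.714
ba     0.655  0.685  0.621
kappa  0.310  0.369  0.245
```

Each of the 3 simulated participants contributes 80 kept trials; the
planted ~8 % fixation-duration shift yields a mean MCC ≈ 0.32 (chance
is 0), i.e. moderate but clearly above-chance decodability — the regime
typical of probe-caught thought classification. `run_full(RunConfig(...))`
runs the same chain for all nine dimensions plus PSO selection and
writes a report comparing all-29-feature and best-10-feature
classifiers.

A CLI mirrors the stages (`gazemind simulate | detect-events |
build-trials | extract-features | classify | pso-select | run-all`).

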