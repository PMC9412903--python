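# rhythmrec

Two-stage clinical decision support for atrial-fibrillation rhythm-strategy
selection, plus a synthetic patient-cohort simulator for testing and
evaluation.

The action space is the four management strategies — rate control (RAC),
external cardioversion (EXC), antiarrhythmic medication (AAM), and AF
ablation (AFA). Patient context is eight clinical features: age, AF duration,
heart-failure history, left-atrial enlargement, resting heart rate,
hypertension, BMI, and symptomatic status.

**Stage 1 (supervised mimicry).** A linear score per action trained by
per-record stochastic gradient descent (learning rate 0.1) against the
clinician's chosen strategy, emitting the frequency at which an expert would
pick each strategy. Softmax cross-entropy is the default loss; a squared
error mode against one-hot labels (`mse_onehot`) is also provided.

**Stage 2 (reinforcement learning).** Linear Q-learning over the same
features: each treatment decision is a single-step episode whose reward is
`-2*stroke - hospitalization - symptomatic_recurrence` from follow-up.
Updates use learning rate 0.01 and are delivered in batches of 8 patients
(per-experience deltas computed at pre-batch weights, then averaged).

**Recommendation surface.** The two stages blend linearly in accumulated RL
experience: `freq = (1-beta) * sl + beta * softmax(Q/tau)` with
`beta = min(1, n/N)` (default N = 500).

**Synthetic worlds.** Since no patient data ship with the package, cohorts
are drawn from configurable worlds with a known ground-truth expert policy
and outcome model: a continuous `default` world (emulating the 100-patient
initialization cohort), a `suboptimal-expert` discrete world (the expert is
deliberately wrong in one context, so the RL stage can demonstrably beat
mimicry), and a `discrete-oracle` world whose expected rewards are exact by
enumeration. YAML copies live in `worlds/`.

## CLI

```bash
# draw a labeled synthetic cohort (optionally with follow-up outcomes)
rhythmrec simulate --world default --n 500 --seed 1 --out cohort.csv
rhythmrec simulate --n 64 --seed 2 --out followup.csv --with-outcomes

# the 100-record initialization cohort + starting SL model
rhythmrec init --seed 0 --out-cohort init.csv --out-model sl.json

# train each stage
rhythmrec train-sl --cohort cohort.csv --out sl.json --lr 0.1 --epochs 50 --seed 0
rhythmrec train-rl --cohort followup.csv --sl-model sl.json --out q.json \
    --lr 0.01 --batch-size 8

# per-patient recommendation (JSON to stdout; --text for a report)
rhythmrec recommend --patients one.csv --sl-model sl.json --q-model q.json

# evaluation and learning curves
rhythmrec evaluate --world suboptimal-expert --sl-model sl.json --q-model q.json
rhythmrec learning-curve --world discrete-oracle --checkpoints 0,1000,10000 \
    --seed 1 --out curve.csv
```

All randomness flows from explicit `--seed` flags; reruns with the same
seeds reproduce outputs byte-for-byte. Usage errors exit 2, data errors
exit 1.

Patient CSV schema (header required):
`patient_id,age,af_duration_months,heart_failure,la_enlargement,resting_hr,hypertension,bmi,symptomatic,expert_action,stroke,hospitalization,symptomatic_recurrence`
— `expert_action` (RAC|EXC|AAM|AFA) and the three outcome flags may be empty.

## Layout

- `src/rhythmrec/core.py` — domain types, validation, feature encoding, reward
- `src/rhythmrec/sl.py` — supervised mimicry stage (SGD)
- `src/rhythmrec/rl.py` — Q-learning stage (batched updates)
- `src/rhythmrec/recommender.py` — blended decision surface
- `src/rhythmrec/synthetic.py` — cohort simulator + named world fixtures
- `src/rhythmrec/evaluation.py` — agreement, policy value, regret, curves
- `src/rhythmrec/io.py`, `src/rhythmrec/cli.py` — file formats and CLI
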