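# cathsim

Headless, scriptable catheter-insertion training simulator for the epidural
space: cognitive-map scenario graphs with hierarchical route selection, a
tube virtual fixture with excursion-based collision scoring, catheter
session kinematics, an orthographic fluoroscopy-style projection, synthetic
trainee agents with learning dynamics, and the mixed-design
repeated-measures evaluation statistics — all reproducible from a single
seed, with no GUI or hardware dependencies.

## What it models

Training content is a small landmark hierarchy: primary landmarks **A**
(start, sacral hiatus), **B** (dorsal→ventral detour point) and **C**
(destination, the lesion disc), with the sacral nerves **S1–S4** as
secondary reference points. Four guided scenarios thread a centerline
through these landmarks (scenario 1: `A→S4→S3→B→S2→S1→C`; scenarios 3–4
omit B) and wrap it in a tube virtual fixture; a *free* scenario has no
fixture and scores collisions against analytic organ primitives (dura,
nerves, discs, bone). Route selection is hierarchical: primary hops first,
then each leg solved independently on the landmark graph.

Synthetic trainees follow the path with Gaussian angular noise whose
standard deviation decays exponentially with repetition; beginner and
expert profiles differ in initial noise and learning rate. Session records
(collision count, completion time) feed a balanced mixed-design
repeated-measures ANOVA (group × repetition, Greenhouse–Geisser optional),
learning-curve fitting, and noncentral-F power analysis — all implemented
from first principles and validated against independent oracles.

The environment geometry is procedurally generated and entirely synthetic;
its dimensions are plausible magnitudes, not anatomical measurements, and
every parameter is overridable.

## CLI

One executable, `cathsim`, with five subcommands:

```bash
cathsim gen-env --seed 0 -o environment.json      # synthetic environment
cathsim run --scenario 1 --agent perfect --out-dir out       # one session
cathsim run --scenario free --agent beginner --seed 2 --out-dir out
cathsim study --n-per-group 8 --reps 20 --seed 0 --out-dir study
cathsim analyze --results study/results.csv --out-dir analysis
cathsim fluoro --scenario 1 --view lateral -o view.pgm
```

Every run writes its resolved configuration next to its outputs
(`resolved_config.json`); identical seeds give byte-identical CSV/JSONL/PGM
outputs. Results CSV columns: `trainee_id, group, scenario, repetition,
n_collisions, completion_time_s, completed, seed`. Collision events stream
as JSONL; images are 8-bit binary PGM (P5).

## Package layout

| module | contents |
| --- | --- |
| `cathsim.scenario` | landmarks, cognitive-map graph, scenarios, hierarchical routing, JSON I/O |
| `cathsim.anatomy` | procedural environment, organ primitives, signed distances |
| `cathsim.fixture` | tube fixture, centerline queries, excursion collision events, penalty force |
| `cathsim.session` | catheter state, step kinematics, session loop, scoring, results CSV |
| `cathsim.fluoro` | orthographic projection and PGM rasterization |
| `cathsim.agents` | trainee profiles, noise schedule, controllers, cohort simulation |
| `cathsim.stats` | group summaries, mixed-design RM-ANOVA, learning curves, power analysis |
| `cathsim.cli` | `gen-env` / `run` / `study` / `analyze` / `fluoro` |
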