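# siglognorm

Sigma-lognormal analysis of rapid pen movements, with a pre/post-fatigue
statistical pipeline. The package

- models planar stroke velocity as a vector sum of lognormal impulse
  responses (command time `t0`, amplitude `D`, log-timing `mu`/`sigma`,
  start/end angles) and derives the per-component timing parameters
  (mode, median, time delay, response time, asymmetry) plus reaction and
  conduction times;
- simulates seeded synthetic tablet sessions (simple strokes, triangles,
  horizontal/vertical oscillations) whose population statistics follow the
  published group tables, with embedded ground truth and optional velocity
  noise at an exact SNR;
- decomposes recorded trajectories greedily into lognormal components with
  a 25 dB SNR stopping criterion, joint refinement, backfitting and
  multistart rescues (`Nblog`, `SNR`, `SNR/Nblog` quality figures);
- formats extracted components (agonist/antagonist classification, triangle
  stroke assignment, oscillation phase splitting, 50 mm artifact filter,
  mean +/- 3 SD outlier rejection, rhythm intervals);
- runs the statistical battery: individual Mann-Whitney comparisons with
  Bonferroni control, a permutation paired Hotelling T^2 gate, group
  signed-rank tests, Cohen's d on the verbal magnitude scale, Spearman
  correlation matrices and population summary percentages.

## Command line

```sh
# simulate a session and write trajectory CSVs plus a manifest
siglognorm simulate --seed 1 --out session/

# decompose every trial referenced by the manifest
siglognorm extract --manifest session/manifest.json --out extracted/

# classify roles/phases and filter outliers
siglognorm format --components extracted/components.csv \
    --trials extracted/trials.csv --out classified.csv

# statistical battery -> report JSON
siglognorm analyze --classified classified.csv --trials extracted/trials.csv \
    --seed 1 --out report.json

# all-in-one
siglognorm run --seed 1 --tests simple,triangle --fatigue ER --out results/
```

Configuration is YAML overriding the scalar population settings
(`n_participants`, `strokes_per_test`, `oscillation_duration_s`,
`sample_rate_hz`, `noise_snr_db`, ...). Trajectory CSVs are
comma-separated with `#`-prefixed metadata lines (`units_time: s`,
`units_xy: mm`, `sample_rate_hz`).

## Layout

```
src/siglognorm/
  model.py       closed-form lognormal component model + derived parameters
  synth.py       seeded synthetic session generator, noise injection
  extract.py     greedy decomposition, SNR, refinement/rescue machinery
  formatting.py  role classification, phase splitting, filtering, rhythm
  stats.py       rank tests, permutation Hotelling T^2, effect sizes, summaries
  pipeline.py    simulate -> extract -> format -> analyze orchestration
  io.py          trajectory CSV dialect, manifests, report JSON, config
  cli.py         click command line
```
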