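# arbitrl

Simulation, model fitting and arbitration metrics for a 2-choice, 3-stage
Markov decision task with *specific* (single rewarded coin color) and
*flexible* (all colors rewarded) goal conditions.

The package provides:

- **task** — subject-specific decision trees (1 root, 4 stage-2, 8 terminal
  states by default; coins 0/10/20/40 colored gray/yellow/red/blue),
  main-phase block schedules (56 blocks, 14 per condition × uncertainty
  type, ~280 trials), a training-phase generator (80 flexible + 20 specific
  trials), probabilistic transition sampling (0.9/0.1 low, 0.5/0.5 high
  uncertainty), and a backward-induction optimal-policy oracle.
- **learners** — a model-free SARSA learner (reward-prediction-error
  updates, discount fixed at 1) and a model-based learner (state-prediction
  -error transition learning plus backward planning under the current goal
  rule), with softmax action selection.
- **fitting** — per-subject maximum-likelihood estimation of
  (learning rate, inverse temperature) per learner by Nelder–Mead from 200
  random restarts, with per-trial likelihood traces. Session replay is
  JIT-compiled with numba when available (pure-Python fallback included).
- **metrics** — MB preference (% of trials where the MB per-trial
  likelihood beats MF), system-switching rate, arbitration score
  (specific/flexible preference ratio), mean coins and choice optimality.
- **agents** — synthetic subjects (random / pure-MF / pure-MB / mixtures
  with condition-dependent weights, lapses, missing trials) and cohort
  generation with a ground-truth parameter table.
- **stats** — one-way ANOVA / ANCOVA with uncorrected and Tukey-style
  post-hoc comparisons, Welch option, paired t-tests and Pearson
  correlations.
- **io / cli** — CSV/JSON/YAML readers and writers and an end-to-end
  pipeline with a reproducibility manifest.

## CLI

```sh
arbitrl gen-task --tree-seed 1 --schedule-seed 2 --out task.json
arbitrl simulate --cohort cohort.yaml --seed 1 --out sessions/
arbitrl fit --session sessions/intact_000_session.csv \
            --tree sessions/intact_000_tree.json \
            --learner mb --restarts 200 --seed 1 --out fit.json
arbitrl metrics --fits fits/ --sessions sessions/ --out metrics.csv
arbitrl stats --metrics metrics.csv --groups group --out stats.json
arbitrl run --config run.yaml --seed 1 --out outdir/
```

Example `run.yaml` / `cohort.yaml`:

```yaml
n_per_group: 4
n_restarts: 20
fit_seed: 0
groups:
  intact:   {kind: mixture, condition_dependent_w: [1.0, 0.0]}
  impaired: {kind: mixture, condition_dependent_w: [0.6, 0.4]}
```

Exit codes: 0 ok, 1 user error, 2 internal error.

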