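# revlearn

Simulation, computational modelling and statistics for **feature-based
reversal learning** behaviour in a two-alternative choice task.

Two stimuli appear left and right of fixation, carrying opposite colours and
opposite motion directions; only colour predicts reward, and the
colour-reward mapping reverses un-cued between blocks of 30–50 trials
(blocks advance once a 12-trial running reward average reaches 90%, checked
from trial 30, or at the 50-trial cap). The package provides:

- **`revlearn.task`** — the task simulator: session/block/reversal structure,
  agents (eight learning models, plus `random` and `perfect` baselines) and a
  validated TSV trial-table format.
- **`revlearn.models`** — eight learning models over the six elementary
  feature values (left/right, up/down, colour 1/2): `FV`, `FV+Decay`,
  `FV+2Eta`, `BI` (Bayesian integration, fixed reward reliability
  `p_r = 0.99`), `FW` (Bayesian feature weighting), `FW+ChoiceHistory`,
  `FW+2Eta` and `FW+Decay`. Each exposes choice probabilities, per-trial
  choice log-likelihood and state updates.
- **`revlearn.fitting`** — maximum-likelihood fitting (multi-start simplex
  warm-up + bounded gradient refinement, numba-accelerated likelihood
  kernel), 80/20 block-level cross-validation, AIC model comparison,
  cross-replicate parameter correlations and model-vs-behaviour SSD curves.
- **`revlearn.observer`** — state-space (random-walk + Bernoulli) estimation
  of the trial-wise probability of a rewarded choice with EM-estimated state
  noise; the learning trial is the first trial whose one-sided confidence
  bound stays above chance for the rest of the block.
- **`revlearn.stats`** — trial-wise permutation test with a pooled-null
  familywise threshold, sliding-window randomization test for the
  consistency of learning differences, and descriptive performance metrics.
- **`revlearn.cli`** — a `revlearn` command with `simulate`, `fit`,
  `analyze` and `recover` subcommands, YAML configuration and reproducibility
  manifests.

## Command line

```bash
# simulate both configured conditions into a trial TSV
revlearn simulate -c config.yaml --out runs/trials.tsv

# fit all eight models per condition with cross-validation
revlearn fit -c config.yaml --trials runs/trials.tsv --out runs/fits

# learning curves, learning-trial distributions, permutation statistics
revlearn analyze -c config.yaml --trials runs/trials.tsv --out runs/analysis

# simulate from the configured generative parameters and refit
revlearn recover -c config.yaml --seed 7 --out runs/recovery
```

A minimal `config.yaml` (all keys optional; defaults shown in
`revlearn.config`):

```yaml
seed: 1
conditions:
  control:
    model: FW+Decay
    params: {eta: 0.561, beta: 2.18, alpha: 0.44, omega: 1.043}
    n_sessions: 19
    blocks_per_session: 8
  drug:
    model: FW+Decay
    params: {eta: 0.648, beta: 2.12, alpha: 0.41, omega: 1.179}
    n_sessions: 19
    blocks_per_session: 8
models: [FV, FV+Decay, FV+2Eta, BI, FW, FW+ChoiceHistory, FW+2Eta, FW+Decay]
cv: {n_reps: 100, train_frac: 0.8}
perm: {n_perm: 1000, level: 0.95}
```

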