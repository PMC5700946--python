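# featlearn

Tools for studying **feature-based versus object-based reward learning** in
multi-dimensional choice environments: when options are bundles of features
(a red square, a striped triangle), a learner can estimate one value per
whole option, or one value per feature instance and combine them. Feature
values update on every relevant trial and generalize across options, so
feature-based learning adapts quickly without raising the learning rate —
but in environments where feature combinations break the feature rules, only
object-based learning is accurate. This package implements the full
computational pipeline around that tradeoff, for computational cognitive
scientists and modelers of learning and decision making.

## What's inside

- **Environments** (`featlearn.environments`) — factorial reward matrices
  built from per-feature odds ratios (`OR(O) = prod OR(F)`,
  `p = OR/(1+OR)`), degraded by within-slice shuffling, scored by a
  *generalizability index* `g`: the correlation between actual object reward
  probabilities and their reconstruction from feature marginals via the
  Bayes odds rule `p~ = prod(p_i) / (prod(p_i) + prod(1-p_i))`.
- **Idealized learners** (`featlearn.framework`) — object- and
  feature-based delta-rule learners, the pairwise differential signal
  `S(t) = (1/(D(D-1))) sum_{a,b} (V_a - V_b) sign(p_a - p_b)`, and the
  *cross-over point* at which object-based learning overtakes.
- **Task designs** (`featlearn.tasks`) — the dynamic reversal tasks over
  four colored shapes (48-trial blocks, super-block structure) and the
  static 3x3 / 4x4 tasks with full feedback and probability-estimation
  blocks.
- **RL models** (`featlearn.models`) — seven trial-by-trial models
  (object/feature x uncoupled/coupled x decay, plus an attentional
  variant), with compiled likelihood replay and agent simulation.
- **Fitting** (`featlearn.fitting`) — multi-start simplex maximum
  likelihood with bounded transforms, AIC/BIC, simulate-and-refit model and
  parameter recovery, early/late goodness-of-fit contrasts.
- **Behavioral metrics** (`featlearn.metrics`) — performance curves,
  chance-exclusion thresholds, win-stay/lose-stay style differential
  responses (object- and feature-based), estimation regression and
  correlation analyses.
- **Network models** (`featlearn.networks`) — parallel (PDML) and
  hierarchical (HDML) decision-making-and-learning circuits with binary
  stochastic synapses at mean-field level, plus environment sweeps.
- **Synthetic cohorts** (`featlearn.cohort`) — whole simulated-subject
  datasets (trial logs + estimation records) with known generating models.

See `docs/methods.md` for the model equations, parameter conventions, and
design choices.

## Worked example

```python
import numpy as np
from featlearn import (FeatureSpace, build_generalizable_matrix, shuffle_matrix,
                       generalizability_index, simulate_framework, crossover_point)

space = FeatureSpace(m=2, n=3, x=2.0)     # 2 features, 3 instances, max OR 2
env = build_generalizable_matrix(space)
print(np.round(env.p, 3))
print("g =", generalizability_index(env).g)

shuffled = shuffle_matrix(env, informative_feature=0, seed=4)
print("shuffled g =", round(generalizability_index(shuffled).g, 3))

for mat in (env, shuffled):
    trace = simulate_framework(mat, alpha=0.05, n_trials=1200, n_runs=200, seed=7)
    print(f"crossover after {crossover_point(trace):.0f} trials "
          f"(S_F[50]={trace.S_F[49]:.3f}, S_O[50]={trace.S_O[49]:.3f})")
```

Output:

```
[[0.2   0.333 0.5  ]
 [0.333 0.5   0.667]
 [0.5   0.667 0.8  ]]
g = 1.0
shuffled g = 0.613
crossover after 372 trials (S_F[50]=0.122, S_O[50]=0.056)
crossover after 82 trials (S_F[50]=0.064, S_O[50]=0.056)
```

The fully generalizable environment (`g = 1`) rewards each object according
to the product of its feature odds ratios, so the feature-based learner's
reconstruction orders all nine objects correctly and it carries more
information (`S_F > S_O`) for 372 trials before the object-based learner
overtakes. Shuffling within the informative feature lowers `g` to 0.61;
feature-based learning then helps only briefly (82 trials): the less
generalizable the environment, the sooner object-based learning wins.

A command-line interface mirrors the library
(`featlearn gen-env | gen-task | gen-cohort | simulate-framework |
simulate-agent | simulate-network | fit | recover | metrics | sweep`);
every stochastic command takes an explicit `--seed` and reruns are
byte-identical.

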