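# Methods

This note documents the models implemented in `featlearn`, the choices made
where the underlying procedures were open, and what the synthetic data do
and do not establish.

## Reward environments

An environment assigns a reward probability to each of the `D = n**m`
objects of a factorial feature space (`m` features, `n` instances each).
Fully generalizable environments are built multiplicatively from odds
ratios: each feature carries the log-spaced grid `{1/x, ..., x}` (`x > 1`;
odd `n` includes an exactly neutral OR of 1), an object's odds ratio is the
product over its instances, and `p = OR / (1 + OR)`.

A feature-based observer reconstructs object values in two steps: the
marginal value of a feature instance is the mean probability over the
`n**(m-1)` objects containing it, and marginals are combined across features
with the odds form of Bayes' rule under a uniform prior,
`p~ = prod(p_i) / (prod(p_i) + prod(1 - p_i))`.

**Generalizability index.** `g` is the correlation between the actual
probabilities and their feature-based reconstructions. The default
correlation is a tie-insensitive rank statistic (Goodman–Kruskal gamma:
concordant minus discordant strictly ordered pairs over their sum). The
reason is a subtlety of the factorial construction: for even `n >= 4`,
distinct instance combinations produce exactly tied object probabilities
(equal OR products) whose probability-averaged reconstructions differ
slightly, so Spearman's average-rank treatment of ties yields `g ~ 0.995`
for a *fully generalizable* matrix. Gamma ignores tied pairs and equals 1
exactly whenever the reconstruction reverses no strict ordering — the
defining property of full generalizability. Spearman and Pearson are
available via `method=`. A constant matrix has no defined correlation and
reports NaN rather than 0.

**Shuffling.** Partially generalizable environments permute entries
independently within each slice of one retained ("informative") feature,
preserving that feature's marginal means exactly; passing
`informative_feature=None` permutes all entries, which is how the
lowest-`g` environments are reached. `environment_with_g` draws shuffles of
both kinds and returns the candidate closest to a target `g`
(deterministic given the seed). Morphing interpolates two environments'
probabilities entrywise.

A note on random environments: under any exchangeable randomization of the
object probabilities, the feature reconstruction is a (rank-)projection
onto an additive subspace of dimension `m(n-1)`, so the expected squared
correlation scales like `m(n-1)/(n**m - 1)` — it *decreases* with `m`.
The distribution of `g` over independently shuffled environments therefore
does not shift upward with dimensionality under this generator (see the
corresponding red acceptance check).

## Idealized learners and the crossover point

Both learners start all values at 0.5 and apply
`V <- V + alpha (r - V)` to the chosen object (object-based) or to every
feature instance of the chosen object (feature-based); the feature-based
learner values objects through the Bayes odds combination of its feature
values (clamped to `[1e-6, 1 - 1e-6]` before combining). The differential
signal `S = (1/(D(D-1))) sum_{a,b} (V_a - V_b) sign(p_a - p_b)` (with
`sign(0) = 0`) measures how well current values order objects by true
probability; it collapses to `2 c.V / (D(D-1))` with
`c_a = sum_b sign(p_a - p_b)`, which the simulator exploits.

The choice policy during these simulations is not part of the learner
definition; the default draws a uniform random pair each trial and chooses
through a logistic on the learner's own estimated values with
stochasticity 0.1 (a `policy="random"` alternative exists). Both learners
share the random draws within a run, so at `m = 1` — where the two models
coincide — their trajectories are bitwise identical. The crossover point is
the first trial (0-based, on run-averaged signals, no smoothing) at which
the object-based signal exceeds the feature-based one: 0 means object-based
learning dominates from the onset, infinity that it never catches up within
the horizon.

## Task designs

**Dynamic two-feature tasks (Experiments 1/2 style).** 2 sessions x 384
trials in 48-trial blocks over a 2x2 space. Generalizable schedules assign
{0.9, 0.7, 0.3, 0.1} so the informative feature splits {0.9, 0.7} vs
{0.3, 0.1} and the secondary feature selects the larger value within each
split; non-generalizable schedules assign the same four values so the
informative-feature means are {0.6, 0.4}, the secondary means are exactly
{0.5, 0.5}, and rank order is violated (e.g. the preferred color holds both
the best and the worst object). Consecutive blocks reverse the preferred
informative instance; the secondary assignment flips at every 4-block
super-block boundary. The exact schedule tables of the original
experiments are not available as numbers; this reconstruction satisfies
every documented constraint and can be overridden with an explicit
schedule table.

**Static tasks (Experiments 3/4 style).** 3x3 (280 trials/session) and 4x4
(336 trials/session) spaces, two sessions, reward feedback for both
presented objects, pairs always differing in both features, and estimation
blocks on a 5–95% grid in 10% steps after the stated choice-trial counts
(the 4x4 variant scales the 3x3 positions by 336/280, since its positions
are not published). Objects at `p = 0.5` (one of 9; four of 16) are
excluded from play. The packaged reward matrices are *synthetic stand-ins*
constructed by search to satisfy every published constraint
simultaneously: non-informative slice means exactly 0.5, distinct and
predictive informative-feature means (~0.25–0.75), the stated number of
excluded `p = 0.5` objects, rank-order violations, and a Pearson
generalizability of exactly 0.57 (3x3) and 0.76 (4x4) — the published
values. The calibration uses Pearson because the printed values are
unreachable by Spearman under the published constraints (the attainable
Spearman set on 9 heavily tied values skips 0.57). Transcribed matrices
can be passed in to replace the stand-ins.

Burn-in exclusions follow the published analysis: the first 10 trials of
each 48-trial block (leaving 608 of 768) or the first 30 trials of each
session (leaving 500 of 560, and 612 of 672).

## Trial-by-trial RL models

Seven models combine a representation (object or feature), coupling, decay,
and an attentional variant:

| model | free parameters | k |
|---|---|---|
| object, uncoupled | alpha_rew, alpha_unr, sigma, bias | 4 |
| object, coupled | alpha_rew, alpha_unr, sigma, bias | 4 |
| object + decay | + d | 5 |
| feature, uncoupled | alpha_rew, alpha_unr, w per feature, bias | m+3 |
| feature, coupled | same | m+3 |
| feature + decay | + d | m+4 |
| feature + decay, attentional | alpha per feature, d, w per feature per session, bias | 2m+2 (one session: m·s weights) |

Updates: chosen values move toward the outcome with `alpha_rew` (rewarded)
or `alpha_unr` (unrewarded); coupled models move the unchosen value in the
opposite direction; decay relaxes every value not updated on a trial toward
0.5 with rate `d` (after the learning update, every trial). When the two
options share a feature instance, only the unique feature of the chosen
object is updated (the always-update variant is available behind a flag for
replicating its known inferiority). Choice probabilities are logistic in
the scaled object-value difference (`/sigma + bias`) or in the weighted
feature-value differences (one weight per feature; a feature model with one
nonzero weight `w` equals the object rule with `sigma = 1/w`).

Conventions: values start at 0.5; they carry across sessions in the dynamic
tasks (same stimuli) and reset between sessions of the static tasks (new
stimulus sets); in full-feedback tasks the uncoupled models update both
presented options, each with its own delivered outcome, while coupled
models keep the anti-correlation rule driven by the chosen outcome; no
reset at block reversals (unsignaled); the observed-choice probability is
floored at 1e-10; feature weights are unconstrained in sign. The replay and
simulation loops are compiled (numba); a pure-Python replay oracle in the
test suite pins their agreement to 1e-10.

## Fitting and validation

Fitting minimizes the total negative log likelihood by Nelder–Mead simplex
from at least 10 randomized starts (default), with bounded parameters
optimized through monotone transforms — logit for rates and decay, log for
sigma — so the search cannot leave the valid region; starts are drawn
uniformly in natural space (rates 0.02–0.5, decay 0.002–0.08, sigma
0.03–0.5, bias ±0.5, weights 0.5–12). `AIC = 2k + 2(-LL)`,
`BIC = k ln N + 2(-LL)`; outputs report both the total and per-trial -LL.

Model recovery simulates agents on the validation grid (learning rate
0.05–0.4, decay 0.005–0.04, stochasticity 0.05–0.4; feature agents receive
weights `1/sigma`), refits all candidates, and tabulates modal BIC winners
per cell. Two systematic confusions are expected and real: at high choice
stochasticity or minimal decay, the decay models are statistically
indistinguishable from their nested no-decay counterparts (the richer model
attains lower raw -LL, but `2 dLL < ln N`, so BIC correctly prefers
parsimony). The aggregate diagonal remains dominant; per-family
(object vs feature) recovery is essentially perfect away from the
equivalence case `m = 1`.

The early/late goodness-of-fit contrast smooths per-trial -LL streams with
a 20-trial moving average and reports the mean of
`(-LL_object) - (-LL_feature)` over trials 1–100 minus the same mean over
the remainder (boundary configurable; chance reference `ln 2` per trial).

## Behavioral metrics

The chance-exclusion threshold is `0.5 + 2 sqrt(0.25/N)` (binomial null
s.e.m.; the only formula reproducing the three published thresholds
0.5406, 0.5447, 0.5404 after 4-decimal rounding). The object-based
differential response is win-stay minus lose-stay for the previously chosen
object. The feature-based differential response conditions on trials whose
pair contains exactly one object sharing exactly one feature with the
previously chosen object and one object sharing none (the pair may not
contain the previous object itself); it is the probability of choosing the
sharer after a reward minus after a non-reward, optionally split by which
feature is shared. Estimation analyses regress reported probabilities on
the actual probability, the feature-based reconstruction, and a constant
(relative weight `b_obj/(b_obj + b_feat)`; regressors with correlation
above 0.999 — fully generalizable matrices — are rejected as degenerate),
or compare per-subject correlations with the two candidate value maps.
Temporal trends over estimation blocks are fit with
`y = a + b exp(-t/tau)`.

## Network models (PDML / HDML)

Value pools (one per object and per feature instance) hold mean-field
synaptic strengths `F in [0, 1]` (the fraction of binary synapses in the
strong state): chosen pools potentiate `F += q+ (1 - F)` on reward or
depress `F -= q- F` on non-reward; all other pools decay toward 0.5 with
`q_d`. The unique-feature rule applies to shared-feature pairs; in
full-feedback tasks both presented objects' pools update, each with its own
outcome. An explicit binary-synapse mode verifies that the mean-field
recursion is the expectation of the per-synapse stochastic rule.

The parallel model (PDML) combines both sets in one final choice with logit
`C_O dF_obj + C_F <dF_feat> / sigma` (`<.>` the per-feature average), makes
two auxiliary decisions from each set alone, and — depending on reward —
potentiates or depresses `C` for each set whose auxiliary choice agreed
with the final choice (disagreeing sets decay). The hierarchical model
(HDML) first selects a set with probability logistic in the *strength*
difference `C_O |dF_obj| - C_F |<dF_feat>| / sigma` (the printed selection
rule uses signed differences, which is not invariant to option relabeling
and contradicts the verbal definition of signal strength; magnitudes are
used), decides with the selected set alone (`dF_obj / sigma` or
`<dF_feat> / sigma`), and updates only the selected set's connection.

The placement of the `1/sigma` gain in the combined choice rule is
typographically ambiguous in its source. The default here is the literal
reading (only the feature term carries the gain); a balanced variant
dividing the whole logit by sigma is available (`scale_whole_logit=True`).
Sensitivity: the literal reading reproduces the fast early growth of the
feature connections, the net positive feature weight, the feature-dominated
fits of hierarchical-model choices in the dynamic task, the
feature dominance of the 4x4 static task, and the performance advantage of
the hierarchical model; the balanced variant reverses the early connection
dynamics and makes both models' choices object-dominated. No reading
reproduces *simultaneously* the dynamic-task phenomena and the
parallel-model "equally fit by both model families" / static-3x3
early-feature-to-late-object transition; the corresponding acceptance
checks are left red rather than tuned.

Defaults: `q+ = q- = 0.15` (value synapses), `0.075` (connections),
`q_d = 0.015` (`0.03` for 4x4-style runs), `sigma = 0.1`, strengths and
connections initialized at 0.5; nothing resets at reversals. Environment
sweeps simulate reversal designs over morphed environments and block
lengths and report harvested reward, terminal `C_F - C_O`, and mean
`W_F - W_O` where `W = C x S` (connection strength times differential
signal of the corresponding value set).

## Synthetic cohorts

Cohorts cycle subjects over specified generating models with parameters
drawn uniformly from the validation ranges. Estimation records are the
agent's internal object values (object models) or the Bayes combination of
its feature values (feature models) at the estimation positions, perturbed
with Gaussian report noise (s.d. 10 percentage points — a fixture choice,
since no subject noise model is published), snapped to the 5–95% grid. A
switching variant drives choices from the feature representation before a
given trial and the object representation after it (both representations
learn throughout), providing ground truth for the transition analyses.

What the synthetic data do not emulate: individual human parameter
distributions, reaction times, attention or session-order effects, and the
exact published reward matrices (constraint-faithful stand-ins, above).
Green tests therefore certify the machinery — constructions, likelihoods,
recovery, and metric definitions — not human-level effect sizes.

## Problem sizes and numerics

The test suite runs every simulation at deliberately modest scale: 200 runs
for learner traces; model recovery on single 384-trial sessions with 10
replicates per grid cell and 6 optimization starts (capped at 250 function
evaluations); parameter recovery with 20 replicates at the primary trial
count and 40 per condition for the trial-count comparison (mean absolute
error, the recovery procedure's error statistic); 25 network runs
(50 sessions) for the fit comparisons, 20 for the static-task contrasts,
and 100 runs per sweep cell. Logistic arguments are
clipped at ±35 in compiled code (±500 elsewhere); probabilities are floored
at 1e-10 inside likelihoods; tie comparisons for the rank correlation round
to 10 decimals to respect exact arithmetic ties under floating point.
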