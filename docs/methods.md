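# Methods

## Task and data model

The package models a stationary two-armed-bandit-style reinforcement
learning task: 60 trials per session, two interleaved stimulus pairs
(30 trials each), one option reinforced at 80% and the other at 20% with
binary 1-euro feedback, a 3-s response deadline, and three within-subject
drug sessions (placebo, L-dopa, haloperidol). Trials with no response
inside the deadline are *misses*: they carry no RT, no reward and — because
no feedback is shown — no value update, and they are excluded from the
likelihood and from all summaries except the miss count.

Canonical storage is a long-format CSV (`subject, condition, pair, trial,
choice, rt, reward`) with `choice ∈ {optimal, suboptimal, miss}`. RTs are
stored in seconds at full float precision so that save/load round-trips are
bit-exact.

Before model estimation the fastest `ceil(0.05·n)` non-miss trials of each
participant-session are discarded so that implausibly fast responses do not
dominate the RT likelihood. The cut is per participant-session, ties on RT
break by trial index (earlier removed first), and the quantile is computed
over non-miss trials only. Filtering is deliberately not idempotent —
re-filtering removes a further 5% of the survivors — and the exact counts
are pinned by tests. Trials removed by the filter still carry observed
feedback, so by default they continue to drive Q-value updates during
likelihood evaluation (`q_update_filtered=True`; a switch on the model
builder).

## Learning and diffusion model

Q-values start at 0.5 per option (the expected value of a 1-euro coin under
a flat prior). The chosen option's value updates by `Q ← Q + η·(r − Q)`;
unchosen values never change. Learning rates live in probit space [−6, 6]
and map to (0, 1) through the standard normal CDF; the dual-rate variant
applies η₊ when the prediction error is strictly positive and η₋ otherwise
(a zero prediction error takes the η₋ branch, which leaves the value
unchanged, so the tie-break is observationally neutral — but it is
documented and tested). The trial drift is `v_t = v_coeff·(Q_opt − Q_sub)`;
the null variant DDM₀ uses a constant drift instead.

The Wiener first-passage density is evaluated with the dual-series
representation: the small-time image expansion and the large-time
eigenfunction expansion, choosing whichever needs fewer terms for a target
absolute density error of 1e−7 (term counts from the standard analytic
truncation bounds). The small-time series is summed in log space with the
dominant exponent factored out, so log-densities stay finite far into the
tails. The upper-boundary density is obtained from the lower-boundary
series by reflection (w → 1−w, v → −v), which makes the reflection identity
bit-exact. The diffusion coefficient is fixed at 1; all α and v values are
in that scale. The start point is fixed at w = 0.5 (no pre-learning
response bias).

First-passage sampling uses Euler–Maruyama with a Brownian-bridge crossing
correction per step (the probability that the path crossed a boundary
inside a step although both endpoints are interior), which removes the
leading O(√dt) absorption bias; dt = 1e−3 by default, 1e−4 in validation
tests, where the sampler passes a KS test against the integrated density at
n = 10⁴. Simulated passages beyond the 3-s deadline are emitted as misses
rather than resampled, mirroring the task.

## Synthetic data generator

`synthetic_data` draws subject-level parameters from group Gaussians
(placebo baseline) plus additive per-drug subject-level shifts —
learning-rate shifts act in probit space — and simulates each session on a
randomized schedule with independently predrawn Bernoulli outcomes for both
options at 80%/20%. Draws are rejection-truncated so that α > 0.1 and
τ ≥ 0.05 s in every condition. One master seed is split hierarchically
(population, schedules, diffusion noise) so components are independently
reproducible.

The `illustrative_truth` preset places the group means at α = 2.0,
τ = 0.35 s, v_coeff = 4.0, η₊ʳᵃʷ = −0.8, η₋ʳᵃʷ = −1.3 — scales at which
simulated behavior lands in the plausible band for this task (mean accuracy
.7–.95, median RT .5–1.2 s) — and uses drug-shift means on the scale of the
reported drug effects. These values are illustrative defaults for
demonstrations and recovery studies, not estimates of any real dataset.
What the generator does *not* emulate: fast-guess contamination, attention
lapses, session-order effects, and any within-session drift of α or τ —
so passing recovery tests show that the estimation machinery works on data
from the assumed model, not that the model is true of real behavior.

## Hierarchical model and priors

Separate mode fits an independent hierarchy per drug condition; combined
mode treats placebo as baseline and adds subject-level Gaussian shift
parameters per drug with group-level shift means (the drug effects) and
SDs. Group means carry uniform priors over numerically plausible ranges —
α ∈ U(0.05, 5), τ ∈ U(0.05, 1), v_coeff ∈ U(0, 20), v_const ∈ U(−10, 10),
η raw ∈ U(−6, 6) — group SDs U(0.001, 3) (η raw: U(0.001, 4)), shift means
N(0, 1), shift SDs U(0.001, 2). All are configurable through `PriorSpec`;
the defaults are package decisions. Drug shifts are subject-level random
effects (not fixed group offsets) for consistency with the rest of the
hierarchy. Non-decision times need no explicit truncation: any retained
trial with rt ≤ τ drives the session likelihood to −∞, which the sampler
rejects, bounding each subject's τ below their minimum retained |RT|.

## Sampler

The posterior is sampled by an adaptive Metropolis-within-Gibbs kernel
(numba-compiled), chains run sequentially from jittered data-driven
initial values:

* group means — conjugate Gibbs (normal, rejection-truncated to bounds);
* group and shift SDs — conjugate Gibbs (σ² | rest is inverse-gamma under
  the uniform-on-σ prior, rejection-truncated);
* shift means — exact Normal–Normal conjugate Gibbs;
* subject parameters and shifts — per-scalar random-walk MH with scales
  adapted in batches of 50 during warmup only (frozen afterwards, so the
  retained chain has the exact target);
* three interweaving moves that break the posterior's stiff directions:
  a baseline/shift *transfer* move (move e into a subject's placebo value
  and −e into all their shifts, leaving drug-condition parameters fixed),
  a per-drug *translation* move (shift the group mean and every subject
  shift of one block together), and a *group-scale* move (rescale subject
  deviations jointly with the group SD, the standard funnel fix).

Session log-likelihoods are cached per (subject, condition) and only
affected entries are recomputed per proposal. `MCMCConfig.paper()` mirrors
the published estimation settings (2 chains, 100k burn-in, thin 2, 10k
retained, R̂ gate [1, 1.01]); `MCMCConfig.desk()` is the reduced
configuration used by every test and script in this repository (typical:
2 chains, 0.8–1.5k warmup, 400–750 retained at thin 2), with an R̂ gate of
1.05. Convergence uses rank-normalized split-R̂ and ESS (arviz) over every
retained parameter. At desk scale the hardest parameters (the weakly
identified negative-learning-rate hierarchy) converge to R̂ ≈ 1.05–1.3;
group-level drug-effect summaries are stable at these settings, but
paper-grade inference should use longer chains.

## Problem sizes

Desk-scale defaults used by the test suite and acceptance script (chosen as
the package's standard demonstration sizes): model-ranking recovery uses 15
subjects × 10 replicate datasets with 2 × (800 + 800) iterations per fit;
drug-effect recovery uses the study-scale 31 × 3 design with 2 ×
(1500 + 1500) iterations; posterior predictive checks simulate 150 datasets
from the posterior with 10 group-level bins (5 individual-level). A full
combined fit at these sizes takes ~1.5 minutes on one CPU.

## Evaluation choices

* PSIS-LOO: importance ratios smoothed with `arviz.psislw`; per-trial
  elpd_i = logsumexp(lw + ll); SE = √(n·var(elpd_i)); Pareto k > 0.7
  flagged. −elpd is reported, smaller = better; exact ties rank by label
  and are flagged.
* HDI: narrowest contiguous window over sorted draws containing
  ⌈mass·n⌉ draws.
* Drug effects: P(effect<0) is the posterior fraction below zero; the
  directional Bayes factor is the posterior odds P(<0)/P(>0) — prior odds
  are 1 under the symmetric zero-centred shift prior — capped at the draw
  resolution (and flagged) when one side is empty. Printed dBFs from
  density-smoothed estimators can differ from posterior-odds arithmetic;
  order-of-magnitude agreement is the design target. The ROPE is ±0.1 ×
  the posterior mean of the placebo group SD of the parameter. No
  multiple-comparison correction is applied.
* Parameter recovery fits use `fast_quantile=0`: the fast-trial filter
  exists to strip fast-guess contamination from real data, and applying it
  to clean simulator output truncates the left RT edge and biases τ upward
  (α downward) by construction. The estimation pipeline for observed data
  keeps the 5% filter.
* Posterior predictive checks compute observed and simulated curves through
  the identical binning code path: equal-count bins by trial position
  within session, both pairs pooled, misses excluded from bin means; bands
  are 2.5/97.5% percentiles across simulated datasets of the per-bin group
  mean. When schedules are not available (real data), the unchosen option's
  outcomes are redrawn at the task rates — the chosen option's outcomes are
  taken from the data.

## Known limitations

* No inter-trial variability parameters, no collapsing bounds, no
  non-linear drift linkage, no starting-point bias: out of scope.
* The sampler is specialized to this model family; it is validated by
  conjugate-step oracles, recovery studies and diagnostics rather than by
  comparison to a generic MCMC engine.
* Euler–Maruyama simulation retains O(dt) RT discretization even with the
  bridge correction; validation uses dt = 1e−4.
* Combined-model fits at desk scale can leave R̂ above 1.01 for
  weakly identified shift-SD parameters; the paper-mode gate exists for
  final inference runs.
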