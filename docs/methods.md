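# Methods

## Task environment

The standard four-deck payoff scheme is generated exactly: rewards of
100/100/50/50 points per draw for decks A–D, with per-10-card blocks
containing five losses of 250 (A), one of 1250 (B), five of 50 (C) and
one of 250 (D), so that every block nets −250/−250/+250/+250.  The
scheme constrains only block aggregates; within-block loss *positions*
are free.  Two policies are provided: `shuffled_block` (default) places
each block's losses uniformly at random within the block, seeded;
`fixed_canonical` uses a fixed documented layout (odd positions
1,3,5,7,9 for frequent-loss decks, the middle card for infrequent-loss
decks) for bit-reproducible fixtures.  Each deck's sequence is long
enough to serve every trial, and decks are consumed independently, so
an agent may draw all 100 cards from one deck.

Losses are stored as non-negative magnitudes; the net outcome is
`gain − loss`.  Before entering any model, outcomes are multiplied by
`outcome_scale` (default 1/100): on raw ±1250-point payoffs the softmax
saturates for most of the parameter ranges, and the 1/100 convention is
the standard one in this model family.

## Randomness

All stochastic stages draw uniforms from a counter-based splitmix64
hash of `(seed, index…)` tuples rather than a stateful generator.  This
makes every result partition-invariant (a grid chunked differently, or
a batch run agent-by-agent, reproduces identical trajectories) and
every synthetic subject replayable from its recorded seed alone.

## Models

ORL and VSE follow the update equations summarized in the README.  Two
conventions the equations do not fix:

* **Initial state is all zeros** for both models, giving uniform
  first-trial choice probabilities.  This is the symmetric, standard
  choice in the field.
* **Update-then-choose ordering**: trial *t*'s choice probabilities are
  computed from the state after trial *t−1*'s update.
* The ORL win-frequency update of *unchosen* decks moves toward
  `−sgn(x)/3` using the learning rate selected by the sign of the
  *chosen* deck's outcome — the only reading consistent with the
  model's single per-trial rate selection.

Parameters are stored on their natural ("primed") scales — learning
rates in [0,1], `K' ∈ [0,5]`, `β ∈ [0,5]` — and the derived quantities
`K = 3^K' − 1` and `c = 3^β − 1` are computed on the fly.  Softmax uses
max-subtraction; exact ties give exactly uniform probabilities.

The legacy baselines (EV, PVL, EV-PU, PVL-Delta) are implemented from
their canonical literature formulations: prospect utility
`x^A` / `−w·|x|^A`, EV's attention-weighted utility `(1−w)W − wL`,
delta-rule versus decay-RL learning, and trial-dependent `(t/10)^c`
versus trait `3^c − 1` sensitivity.  Their grid ranges (shape, rates
and decay in [0,1]; loss aversion in [0,5]; consistency in [0,5], or
[−5,5] for the EV family) are this package's documented defaults; exact
published ranges vary across studies, so legacy parameter-space results
should be read qualitatively.

## Choice-pattern classification

The broad rule assigns the label of the dominant contrast between
`d_value = (C+D) − (A+B)` and `d_freq = (B+D) − (A+C)`; on exact
magnitude ties the frequency dimension takes priority (the
`value_priority` alternative is available via the `rule=` argument of
`classify_broad` / `classify_counts_batch`).  "Remaining" occurs only
when both contrasts vanish, which for near-random or perfectly cycling
agents happens at roughly the multinomial double-tie rate.  The
frequency-priority default was chosen because it reproduces the
empirical ordering of the ORL parameter space (IOF share exceeding BOG)
that a value-priority rule inverts; both rules agree everywhere except
on exact ties.

The restricted rule keeps three patterns and demands the dominant pair
reach 65 of 100 choices (C+D ≥ 65 for GOB, A+B ≥ 65 for BOG, B+D ≥ 65
for IOF; FOI has no restricted tier).  It is defined on 100-trial
sessions; other lengths require explicitly overriding the threshold.
Restricted proportions are reported both raw (fraction of all runs) and
renormalized over qualifying runs.

## Parameter space partitioning

PSP grids each parameter with `n_points` **cell-centered** values (the
midpoints of equal subintervals).  PSP proportions estimate the
*volume* of behavioral regions, for which the midpoint rule is the
natural quadrature; inclusive-endpoint grids put 1/n of an axis's
weight on boundary atoms — a zero punishment learning rate alone, a
measure-zero point of the space, otherwise inflates the Bad-Over-Good
share several-fold at desk-scale resolution.

Unbounded parameters (ORL β_F, β_P; VSE φ) are truncated to [−10, 10]
by default (on the 1/100 outcome scale).  The bound is wide enough that
the frequency/perseverance/exploration terms can dominate the learned
values over most of the gridded range, which is what the near GOB/FOI
symmetry of the ORL space requires; at ±5 the EV term dominates too
much of the β_F axis and the FOI share drops by ~8 percentage points.
Sensitivity to this choice can be surfaced by re-running with
`GridSpec(truncation=...)`.

One 100-trial subject is simulated per parameter set (a replicate
option exists at the API level via repeated runs with different seeds);
per-set randomness is keyed by `(seed, set index)`, so results are
identical under any chunking or worker partitioning.  The desk-scale
default is 10 points/parameter (100,000 sets, ~10 s); the full 60⁵ grid
is supported by the same streaming interface.

At the defaults, the ORL space concentrates on Good-Over-Bad (~41%)
and Frequent-Over-Infrequent (~43%) with small IOF (~9%) and BOG (~7%)
shares.  A faithful VSE implementation does **not** reproduce a fully
balanced four-way split: preferring the frequent-loss decks (FOI) is
rare VSE behavior under every variant we examined (outcome scales 1 to
1/1250, φ bounds ±1 to ±20, β ranges [0,1] to [0,5], value- or
frequency-priority or deck-level classification), because both
exploitation and exploration dynamics drift toward the infrequent-loss
decks.  The VSE space here splits roughly GOB 9 / BOG 9 / IOF 44 /
FOI 26 / Remaining 11 percent; the Remaining share is dominated by
perfect four-deck cyclers whose counts tie exactly.  This is a known
divergence from published characterizations of the model's balance and
is asserted honestly (and currently red) in the acceptance suite.

## Synthetic cohorts

`generate_cohort` rejection-samples simulated subjects against
restricted-pattern include/exclude filters.  Defaults: 20 subjects,
half ORL / half VSE, parameters drawn uniformly over the grid ranges;
the `gob_cohort_spec` / `bog_cohort_spec` presets admit only {GOB, IOF}
(respectively {BOG, IOF}) restricted labels, so the excluded pattern is
absent by construction.  Metadata records each subject's generating
model, parameters, seed and labels, and suffices to replay the cohort
exactly.

For parameter-recovery and model-comparison studies,
`hierarchical_cohort` draws subject parameters from group-level normals
on the unconstrained (probit) scale.  The documented default group
means (unconstrained) are ORL (−0.4, −0.9, −0.8, 1.2, 0.7) and VSE
(0.0, 0.8, −0.3, 0.6, −0.5) — moderate learning, mild perseverance/
frequency weighting, mid-range consistency.  Group SDs follow each
model's own hyperprior scale (0.2 for ORL, whose hyper-SD prior is
half-normal(0.2); 0.4 for VSE, whose half-normal(3.0) hyperprior is
weak), the standard recovery design of simulating from the model's own
hierarchical structure.

What the generator does *not* emulate: real subjects' session effects,
learning breaks, response times, or the parameter correlations of
clinical populations.  Passing recovery tests therefore demonstrates
that the fitting machinery is consistent, not that real IGT data are
identified this well.

## Hierarchical fitting

Subject-level parameters sit under group-level normals in an
unconstrained space; bounded parameters map to their ranges by
`scale · Φ(μ + σ z)` (probit-inverse), unbounded ones by the identity.
Hyperpriors: `μ ~ N(0,1)`; hyper-SDs half-normal(0.2) for ORL's bounded
parameters, half-Cauchy(1) for its two unbounded weights, and
half-normal(3.0) for all VSE parameters.

The default backend is Metropolis-within-Gibbs, exploiting the
hierarchy's conditional structure: subjects are independent given the
group level, so one sweep updates each parameter column across all
subjects with a single batched numba likelihood call; group means are
conjugate normal given subject values (drawn exactly); group SDs take a
log-scale random-walk step requiring no likelihood evaluation.
Proposal scales adapt toward ~35% acceptance during 3000 burn-in sweeps
and freeze; 1000 draws are kept at a thinning of 6 (~3–8 s per
20-subject fit).  Three alternative backends satisfy the same
deterministic contract: an emcee differential-evolution ensemble seeded
from an ELBO-calibrated Laplace Gaussian, that Gaussian itself with
truncated self-normalized importance weights, and a pure mean-field
(diagonal-Hessian) Gaussian.  On recovery benchmarks the mean-field
factorization is markedly underdispersed for group means and the
Laplace variants are fragile on VSE's irregular posterior, which is why
sampling is the default.

WAIC uses the pointwise log-likelihood matrix over all subject-trials:
`WAIC = −2(lppd − p_waic)` with `p_waic = Σ_i var_s(ll_is)`, and
`SE = sqrt(n · var(pointwise contributions))`.  AIC/BIC conventions for
a hierarchical fit are under-determined; this package evaluates the
summed log-likelihood at per-subject posterior-mean parameters with
`k = 5 × n_subjects` and `n =` total trials, and echoes all three
conventions in every result.  `compare_models` declares superiority
only when AIC, BIC and WAIC agree unanimously *and* |ΔWAIC| exceeds the
larger WAIC SE; everything else is "inconclusive".

Degenerate inputs: empty datasets, subjects with fewer than two trials,
and ragged trial counts are rejected; fewer than two posterior draws
make WAIC undefined and raise.

## Problem sizes used in the test suite

Unit tests run on reduced grids (2–8 points/parameter) and small
cohorts (4–10 subjects × 30–60 trials).  The acceptance checks use the
package's reference conditions: 10-point grids (100,000 sets per
model), 20-seed cohort-contract sweeps, and 10 replicate recovery/
comparison cohorts of 20 subjects × 100 trials per generating model —
sizes at which the whole suite completes in a few minutes on one core
while keeping the Monte-Carlo error of the headline proportions near or
below half a percentage point.

## Known limitations

* The VSE parameter-space balance divergence described above.
* The Gibbs backend's adaptation is frozen rather than fully tuned per
  dataset; pathological datasets could need longer burn-in
  (`FitConfig(gibbs_burn=...)`).
* Legacy models' exact published grid ranges vary; their PSP outputs
  are qualitative.
* No response-time modeling; ORL's softmax sensitivity is fixed at 1 by
  construction.
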