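# Methods

## The problem

Computer Vision Syndrome (CVS) is the cluster of ocular and visual
complaints — burning, dryness, blurred vision, headache and so on —
associated with prolonged work at visual display terminals (VDT).  The
validated CVS-Q instrument asks about 16 symptoms, scoring each by a
recode of frequency (0 never, 1 occasionally, 2 often/always) times
intensity (1 moderate, 2 intense): the product {0, 1, 2, 4} is recoded
{0, 1, 1, 2}, the 16 item severities are summed to a total in [0, 32],
and a worker scoring **≥ 6** is classified symptomatic.

Given a cohort of workers described by a few hundred mostly-binary
predictors (demographics, department and shift dummies, ocular history,
seniority, daily screen hours), the package asks: *which variables best
predict the CVS-Q score, and how well can the score be predicted?*

## The model

The predictor is a binary least-squares regression tree

    T(x) = Σ_m  μ_m · B_m(x)

with B_m the indicator of the m-th leaf's path conditions (a product of
split indicators `x_i ≤ c` / `x_i > c`) and μ_m the mean training target
in that leaf.  Trees are grown greedily: each node takes the
(variable, threshold) pair minimising the children's residual sum of
squares, with candidate thresholds at midpoints between consecutive
distinct observed values.  A node stops splitting when its residual
error is zero, it holds fewer than `min_node_size` subjects, no split
strictly reduces the SSE, or `max_depth` is reached.  Ties between
equally good splits break to the lowest column index, then the smallest
threshold, making fits fully deterministic.

Variable *selection* is wrapped around the tree by a genetic algorithm.
A chromosome is a length-p bit mask (1 = the variable may enter the
tree).  Fitness of a mask is the **validation RMSE** of the tree fitted
on the training split restricted to the masked columns — the search
optimises held-out error, not training fit.  The generational loop uses:

* truncation selection — parents drawn uniformly from the better half;
* single-point crossover with probability `crossover_prob`, otherwise
  cloning; offspring repaired if all-zero (one parental bit copied);
* independent per-bit mutation with probability `mutation_prob`;
* elitism — the top `ceil(elitism_fraction · pop)` members copied
  unchanged, making the best-so-far fitness trace non-increasing;
* a stall rule — stop when the best fitness has not improved by a
  relative margin > `stall_tolerance` (default 1e-4, i.e. 0.01%) within
  `stall_generations` (default 100), with a `max_generations` safeguard.

The full protocol repeats this over many independent random 80/20
resamples of the cohort (validation side = ⌈0.2 n⌉, so 343 subjects
split 274/69).  Aggregation yields the method's two outputs:

* **inclusion-frequency importance** — the fraction of replicas whose
  best mask contains each variable; and
* an **error profile** — mean |true − predicted| per true score value
  and the pooled empirical CDF of absolute errors,

plus a plain-tree baseline (same splits, all variables, no GA) for the
selected-vs-full comparison.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `min_node_size` | 5 | smallest splittable node; the growth stopping rule |
| `max_depth` | 12 | hard recursion safeguard |
| `population_size` | 50 | GA population |
| `crossover_prob` | 0.8 | per-pair crossover application probability (method grid 0.5–1.0) |
| `mutation_prob` | 0.1 | per-bit flip probability (method grid 0.1–0.3) |
| `elitism_fraction` | 0.05 | copied-unchanged fraction (grid 0.01/0.05/0.1) |
| `stall_generations` / `stall_tolerance` | 100 / 1e-4 | termination: no >0.01% relative improvement in 100 generations |
| `fraction_train` | 0.8 | resample split |
| `n_replicas` | 1000 | full-protocol replica count |

### Scaled study protocol

The packaged simulation studies (tests and the acceptance script) use a
scaled protocol, exposed as `ensemble.study_ga_config()` /
`study_growth_config()`: population 16, crossover 0.8, **mutation 0.02
per bit**, elitism 0.1, stall 30 within a 200-generation cap, trees with
`min_node_size` 10 and `max_depth` 10, and 50 replicas per study.  Two
of these choices deserve explanation:

* *Gentle mutation.*  On a 60-variable chromosome a per-bit rate of 0.1
  flips ~6 bits per child, which keeps the population pinned near half
  density and prevents convergence toward sparse masks within any modest
  generation budget; at 0.02 (~1 expected flip) the search behaves as a
  population hill-climber and mask composition actually responds to
  selection.  The grid values 0.1–0.3 remain available and are the
  `GaConfig` default.
* *Deeper trees.*  At `min_node_size` 10 / depth 10 the held-out cost of
  carrying noise variables, and the benefit of weak informative ones,
  are both measurably larger than at shallower settings, sharpening the
  fitness signal the GA sees.

## The synthetic cohort generator

The original hospital data were never deposited, so the generator
emulates their published structure: default 343 subjects and 255
predictors — 250 Bernoulli indicators with prevalences in [0.05, 0.95]
(three named history/shift indicators use study-like prevalences:
contact lens 0.155, conjunctivitis history 0.30, rotating night shifts
0.29) plus five continuous exposures (gamma-distributed occupational
seniority ≈ 18.5 ± 11.5 y and unit seniority ≈ 11.2 ± 11.0 y, clipped
normal screen hours at work ≈ 5 ± 2.2 h/d in [0, 12] and outside work
≈ 1.4 ± 1.2 h/d in [0, 8], age ≈ 46.9 ± 10.9 y in [22, 67]).

The target is deliberately **tree-structured** so the estimator family
matches the generator and recovery tests are fair: a base level plus
five threshold effects (seniority > 20 y → +4; screen hours > 4 → +3;
contact lens → +3; conjunctivitis history → +2; night shifts → +2),
plus rounded Gaussian noise (sd 2), clipped to [0, 32].  The base level
(1.2) was calibrated once, by simulation, so the default cohort's
symptomatic fraction sits near the published 56.9%.  With zero noise a
sufficiently deep tree on the true variables reproduces the target
exactly (tested).

Questionnaire emulation decomposes each integer score s = 2a + b into a
items of severity 2 and b of severity 1 (a drawn uniformly from its
feasible range, items randomised); re-scoring reproduces the totals
exactly.

What the generator does **not** model: inter-symptom psychometric
correlation, department/hospital confounding beyond marginal
prevalences, missing data, and any real dependence structure among
predictors (noise indicators are independent).  Passing recovery tests
therefore show the pipeline finds planted tree-structured signal under
realistic dimensions and noise — not that it would rank variables
correctly under arbitrary real-world correlation.

Smaller families used by the studies: the *recovery family*
(`recovery_family_spec`) keeps the default signal and noise but uses 400
subjects and 60 predictors so a 10-master-seed × 50-replica study runs
on one CPU.

## Descriptive layer

Exclusion accounting applies the four eligibility rules in published
order (ocular disease — with sub-reason comorbidity counted once —
non-computer user, out-of-scope occupation, missing seniority),
attributing each record to the first rule it trips; the ledger conserves
counts by construction.  Stratified prevalence uses Pearson chi-square
**without** continuity correction (the convention consistent with the
reference study's printed p = 0.003 for the contact-lens 2×2; the
corrected variant is a flag), with a low-expected-count warning column
when any expected cell is < 5.  Printed-style percentages use half-up
decimal rounding (banker's rounding would break cases like
171/288 → 59.4).

## Numerical choices

* SSE comparisons use a relative slack of 1e-9; splits must beat the
  parent, and each other, by more than it.
* The compiled tree kernel presorts each column once and maintains
  sorted per-column row orders through stable partitioning, so a node's
  best split is one linear scan per column.  It implements exactly the
  same split rule as the pure-NumPy reference `best_split` (asserted
  against brute-force enumeration and against sklearn's achieved SSE in
  tests).
* All randomness flows through `numpy.random.Generator`; replica seeds
  derive from `SeedSequence([master_seed, replica_id])`, so every
  replica is individually reproducible and replicas are independent.
* All-zero chromosomes (from init, crossover or mutation) are repaired
  by setting one random (or parental) bit; every evaluated mask has at
  least one variable.
* Degenerate inputs: constant targets yield a single-leaf tree; columns
  constant within a node are skipped; an empty train or validation side
  is rejected at the split.

## Known limitations

* Fitness is a single 80/20 hold-out per replica, as the protocol
  prescribes — no k-fold mode, no nested validation; reported RMSEs are
  replica-level hold-out errors, not an unbiased generalisation
  estimate for the final refit tree.
* Inclusion frequency is reported raw: no stability-selection error
  control, no significance statement about ranks.
* The GA is single-objective and non-adaptive; no pruning of the final
  trees (no cost-complexity step).
* With few informative variables and weak effects, inclusion fractions
  of uninformative variables hover near one half (mask bits that the
  tree never uses are selectively neutral), so separating a weak true
  effect from the upper tail of ~50 noise variables is the binding
  constraint on recovery studies.
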