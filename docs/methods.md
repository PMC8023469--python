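# Methods

## The model

`ratnet` treats the solution of a Remote Associates Test (RAT) item — find
the one word associatively related to three given stimulus words — as a
search process on a weighted directed free-association network. Nodes are
words; the edge `i -> j` carries `w_ij`, the conditional probability that
participants respond `j` when cued with `i`. Rows of the adjacency matrix
`W` are therefore sub-stochastic (`sum_j w_ij <= 1`), and all computation
in the package flows through this one container.

Two families of search models are implemented.

### Closed-form first-passage probabilities

Zeroing the outgoing row of the response word `r` gives the absorbing
matrix `W-`; the probability that a random walk with jump probabilities
`w_ij`, started at stimulus `s`, reaches `r` for the first time is the
series

    pi_{s,r} = w_{s,r} + sum_{k != r} w_{s,k} w_{k,r} + ...
             = [W- (I - W-)^(-1)]_{s,r}.

A resetting weight `lambda in [0, 1]` — the per-step probability of
continuing rather than abandoning the current chain — multiplies an
N-step walk by `lambda^(N-1)`:

    pi_{s,r}(lambda) = [W- (I - lambda W-)^(-1)]_{s,r}.

`lambda = 0` is the one-step strategy (the direct association weight),
`lambda = 1` the unlimited walk; `pi` is monotone non-decreasing in
`lambda` because every series term is non-negative. The problem-level
probability `p_lambda` averages `pi` over the three stimuli as equally
likely starting points. For `lambda < 1` the total mass is below one (the
search may stop unresolved); the raw series value is returned without
renormalization.

Numerics: the package never inverts the matrix. One sparse LU solve of
`(I - lambda W-) x = e_r` yields the first-passage probability from
*every* source at once via `W- x`; the relative residual must be at or
below 1e-10 or a `SingularTransitionError` is raised (a genuinely
singular system occurs only when a closed recurrent class has exact unit
row sums at `lambda = 1`). Results are clipped to `[0, 1]` against
round-off. The independent oracle (`path_sum_oracle`) enumerates all
directed walks up to a length cap with the interior never visiting `r`,
and reports an explicit geometric remainder bound
`lambda^L s_max^L / (1 - lambda s_max)` (`s_max` = max row sum of `W-`);
the linear solve must land inside `[partial sum, partial sum + bound]`.

### Spreading activation with attraction to the stimuli

The Monte-Carlo simulator keeps the three stimuli permanently active. At
each attempt one candidate `x` — an out-neighbour of the active set that
is neither active nor previously checked — is activated with probability
proportional to its summed input from active words. A wrong activation
becomes the "current guess" (so four words are active from the second
attempt on, and the guess's associations steer the next step) until it is
replaced and permanently marked checked. The run ends on activating the
response (success), exhausting the budget `t_max`, or reaching a dead end.
Model accuracy is the success fraction over replicates; the mean solving
length averages the success attempt index over successful runs only.

Two weak-link manipulations sit on top:

* activation threshold `tau`: candidates whose summed input is below
  `tau` are removed. As printed, the candidate law would leave the
  sub-threshold probability mass unassigned; the package renormalizes
  over the passing candidates so exactly one word activates per attempt,
  which keeps "after t attempts, t words have been checked" true. The
  unrenormalized variant stays available via
  `SearchConfig(renormalize=False)` for sensitivity analysis (a step may
  then activate nothing while still consuming budget).
* strong-link cutoff `w_max`: edges heavier than `w_max` are removed
  statically before searching (`cutoff_experiment`); `w_max = 1` is the
  null model.

Design choices where the process description left room: a dead start or
dead end (no candidate passes `tau`) terminates the run as a failure —
no restarts within a run; checked words are excluded from the candidate
set entirely, not given probability zero; stimuli are never candidates
(they cannot be the answer by construction); sampling happens from the
active set *before* the previous guess is deactivated, so four active
words feed every step after the first.

Reproducibility: every replicate of every problem draws its own 31-bit
seed from a splitmix64 counter chain over (master seed, problem key, run
index), so experiments are order-independent and parallelizable, and
re-runs are bit-identical. The compiled (numba) batch kernel and the
pure-Python `run_search` consume identical legacy MT19937 streams — one
uniform per attempt, candidates scanned in ascending node order — and are
verified to reproduce each other trajectory-for-trajectory. Budget
coupling uses common random numbers: one simulation at the largest
`t_max` records each run's success attempt, so accuracy is exactly
monotone in the budget. The exact verification oracle
(`exact_success_probability`) runs dynamic programming over
(guess, checked-set) states with the same candidate law, guarded at 2^14
reachable states.

## Hardness and correlation

Empirical hardness `H in [0, 1]` is the fraction of subjects solving an
item within 15 seconds (larger = easier). Categories use the half-open
partition hard `[0, 0.32)`, medium `[0.32, 0.64)`, easy `[0.64, 1]`; the
published category descriptions overlap at the boundaries, and this
convention is validated against the published 15/38/85 category counts of
the 138-problem normative bank. Correlations are plain Pearson on raw
(untransformed) predictor values with an OLS line of `H` on the
predictor; constant series are reported as undefined rather than silently
dropped. Problems with any word missing from the network are excluded
with a logged report before an experiment, mirroring the restriction of
the original 144-item bank to the 138 items inside the network's largest
strongly connected component.

## Network characterisation

Topology summaries report the mean in/out degree `E/N`, the arithmetic
mean link weight, the directed unweighted diameter *within the largest
SCC* (the full graph is typically not strongly connected), and the global
clustering coefficient of the undirected unweighted projection — single
scalar conventions chosen because the corresponding published table gives
single scalars without definitions; exact agreement on external data is
therefore not guaranteed. The in-degree tail exponent uses the continuous
maximum-likelihood (Hill-type) estimator
`1 + n / sum(log(k_i / (k_min - 0.5)))`. Percolation curves re-threshold
the network at each cutoff (window `[w_cut, 1]`, inclusive bounds
throughout the package) and report the largest-SCC node fraction relative
to the original node count; the "threshold" is operationalised as the
grid point of steepest drop rather than a hard-coded value, since the
published criterion is visual.

## Synthetic data

The generator targets the marginal statistics the analysis relies on, not
any particular corpus: per cue, a latent candidate pool (size
Poisson-distributed with mean 40) is sampled with probability
proportional to heavy-tailed node attractiveness (classical Pareto with
tail index `attractiveness_exponent = 2`, giving an in-degree density
exponent near 3), weighted by a symmetric Dirichlet
(`concentration = 0.1`), and `m = 100` i.i.d. responses are drawn from
it; weights are count fractions `count/m`. This yields, at n = 10^4:
mean out-degree ~11 with variance/mean ~0.65 (Poisson-like), an
in-degree tail exponent of ~3.0 at `k_min = 10`, a weight floor of
`1/m = 0.01` with many near-floor "measurement noise" edges, and a
minority of strong edges — the regime in which the threshold and cutoff
effects operate. A mean degree this size (rather than the ~30 of the
full-scale empirical network) is what makes the power-law regime visible
above `k_min = 10`; the two constraints cannot hold simultaneously at a
mean degree of 30.

Problems are planted on disjoint word sets. Easy: three direct `s -> r`
links with weights in `[0.2, 0.5]`. Hard: direct links removed, each
stimulus wired through its own two-step path `s -> k -> r` with weights
in `[0.02, 0.06]`. Medium: the two-step paths plus one direct link drawn
from `[0.06, 0.2]` (between the two regimes). Insertions rescale the
source's existing out-weights by `1 - w_new`, preserving sub-stochastic
rows without deleting structure. Reference hardness is *defined* as the
model accuracy of the reference simulator (`t_max = 20`, `tau = 0`,
`w_max = 1`, 10^4 runs) under a seed stream independent of both
generation and later evaluation, optionally plus clipped Gaussian noise.

What passing tests on this data do and do not show: the generator
reproduces degree/weight marginals and the planted easy/hard contrast,
but synthetic words carry no semantics, the network has no community or
multiplex structure, and reference hardness is the model's own accuracy —
recovery experiments therefore validate the pipeline's internal
consistency (seed-independence, estimator correctness), not the
psychological claim that humans search this way.

## Problem sizes and defaults

Shipped experiments use sizes that keep the full suite and the
acceptance script in the minutes range on one core: oracle comparisons on
200 networks of 5–10 nodes (walk enumeration capped at 10^7 partial
walks; per-`lambda` length caps 1/14/16 keep remainder bounds at or
below ~0.04); simulator-vs-DP checks at 10^4 replicates on 6–7-node
fixtures; the recovery study on a 1200-node network with (10, 10, 20)
planted problems, 10^4 replicates per problem, threshold grid
`{0, 0.02, 0.04, 0.06, 0.08}` and cutoff `w_max = 0.05`.

## Known limitations

* The reference problem bank is a synthetic stand-in reproducing only the
  published marginal counts (138 = 15 + 38 + 85); its word labels and
  individual hardness values are not the normative data.
* `summarize_topology` on very large networks computes an exact diameter
  (all-pairs BFS within the SCC), which is expensive at corpus scale.
* The degenerate all-equal tail in the exponent estimator yields a finite
  but meaningless value; it warns instead of failing.
* Monte-Carlo/DP agreement tests use fixed seeds and 3-standard-error
  bands; they are statistical, not exact, guarantees.
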