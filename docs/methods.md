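# Model and methods

## The influence-Leviathan process

Each of `N` agents carries a row of esteems `a[i][·]` on a bounded scale,
with `a[i][i]` its self-esteem; every entry starts at 0 (neutral). The
dynamics are driven by pairwise encounters:

1. draw a focal agent `i` uniformly (with replacement across the `N/2`
   encounters of one iteration, so each agent interacts once on average);
2. draw a partner `j ≠ i` (pairing protocols below);
3. apply, in order, `Influence(i, j)`, `Influence(j, i)`, `Gossip(i, j)`,
   `Gossip(j, i)`, each step reading the state left by the previous one.

A directed `Influence(i, j)` computes the credibility
`p = 1/(1 + exp(−(a_ij − a_ii)/σ_i))` from its own pre-update values and
then moves the listener's self-esteem toward what the speaker thinks of
the listener, and the listener's esteem of the speaker toward the
speaker's self-esteem, each perturbed by independent uniform noise on
`(−δ, +δ)`. A directed `Gossip(i, j)` computes `p` once (it is a
property of the pair, not of the gossip target) and then, `k` times,
draws a target `z ∉ {i, j}` — independently, so targets may repeat — and
moves `a_iz` toward `a_jz` at weight `p`, with fresh noise per update.
Every updated entry is clipped to the esteem bounds (default `[−1, +1]`)
immediately.

This is the influence-only member of the Leviathan family: the "vanity"
process (rewarding flatterers, punishing despisers) is deliberately
absent, and contact is unstructured (no network).

### Pairing protocols

Two partner-selection rules are implemented because they genuinely
differ for unequal groups:

* `group-coin` (default): flip a coin with P(same group) = 0.5, then
  draw uniformly inside the chosen group, falling back to the other
  group when the chosen pool is empty or contains only the focal agent.
  For equal groups this is group-blind contact.
* `uniform`: draw `j` uniformly from all other agents.

For equal groups the two agree to O(1/N). For unequal groups the coin
rule makes minority agents interact roughly `N_other/N_own` times more
often per capita, and that extra churn measurably reshapes the emergent
hierarchy — with a small status-sensitive minority it can even invert
the group ordering. The group-size sweep therefore defaults to
`uniform`, under which the qualitative inequality pattern is independent
of the group split; the single-cell designs use `group-coin`, where the
distinction is immaterial.

## Parameters

| symbol | field | default | meaning |
| --- | --- | --- | --- |
| N | `n_agents` | 40 | population size |
| N_S, N_L | `n_small`, `n_large` | 20, 20 | group sizes (S: small σ) |
| σ_S, σ_L | `sigma_small`, `sigma_large` | 0.1, 0.15 | open-mindedness (logistic slope); dimensionless, on the esteem scale |
| δ | `noise_half_width` | 0.2 | communication-noise half-width |
| k | `gossip_count` | 3 | third parties gossiped about per directed call |
| — | `same_group_prob` | 0.5 | same-group probability under `group-coin` |
| — | `esteem_bounds` | (−1, +1) | clipping interval |
| T | `n_iterations` | 500 000 | horizon; sweeps default to `max(500000, 50000/σ_S)` because small σ_S slows stabilisation |
| — | `measure_every` | 10 000 | snapshot cadence |

The σ_L relations used in the sweeps are `f1: σ_L = 1.5 σ_S` and
`f2: σ_L = σ_S + 0.1` (they agree exactly at σ_S = 0.2). Replica `r` of
a run uses seed `base_seed + r`; sweep cells are offset by
`cell_index × replicas`, so every (cell, replica) pair has a distinct,
order-independent seed.

## Engines and randomness

The production engine is a numba kernel; the per-operation functions in
`leviathan.dynamics` are a deliberately naive, loop-based reference.
Both consume the same `numpy.random.Generator` with an identical draw
discipline — every integer choice is `floor(u·m)` from one uniform draw,
never `Generator.integers` — so the two paths are bit-identical from a
shared seed (asserted in the test suite over a 6-agent, 100-iteration
run, and exploited throughout as an oracle). The `floor(u·m)` map
carries an O(m/2⁻⁵³) bias, irrelevant at these population sizes. The
scalar credibility path uses `math.exp` so that the reference and the
compiled kernel share the same libm call.

Fixed (params, seed) reproduce snapshot series bit-identically; CSV
floats are written at 10 significant digits so output digests are stable
too.

## Indicators

* **Reputation** of `j`: mean of column `j` excluding the diagonal — the
  esteem accorded by *others*; self-esteem never contaminates it.
* **Group aggregates**: arithmetic means over group members; population
  (not sample) standard deviations throughout, as these are descriptive
  statistics over whole groups of ≤ 40 agents.
* **Variation coefficient**: population SD divided by the *absolute*
  group mean. Mean esteems are typically negative here; a signed CV
  would invert the group ordering. Both the self-esteem CV and the
  reputation CV are emitted as separate columns, since intra-group
  stratification is discussed in terms of each.
* **Social rank**: 1 = best reputation, N = worst, ties broken by
  ascending agent index (ties are measure-zero once noise acts; the rule
  keeps the noise-free case deterministic).
* **Stationary window**: the trailing 50% of snapshots (configurable per
  series). All pooled indicators — occupancy, advancement, glass
  ceiling, Z-scores — pool (snapshot, replica) observations from this
  window.
* **Advancement probability**: P(rank at the next *measurement* ≤
  current rank | group, current rank); "next" is the next snapshot, not
  the next micro-iteration.
* **Extreme-rank Z-score**: with q the group's population share and n
  pooled extreme-rank slots of which the group holds X,
  `Z = (X − nq)/√(nq(1−q))`. The binomial null treats pooled slots as
  independent; consecutive snapshots are in fact autocorrelated, so |Z|
  is an overstatement of evidence and only the sign and relative
  magnitude should be interpreted. (The null form is this package's
  choice; the quantity it standardises — deviation from proportional
  representation in the top-5/bottom-5 ranks — is the designed estimand.)

### The glass-ceiling rank

Two estimators are provided:

* `glass_ceiling_rank` (default, `method="occupancy"`): the best rank at
  which the disfavoured group's occupancy probability reaches its
  population share `q = N_L/N`. Above this rank the group is
  under-represented at every position, with occupancy decaying toward
  zero at the very top; below it the group holds at least its
  proportional share. The threshold `q` is fixed by the design, so the
  estimator has no free parameter. In the default equal-group regime it
  sits at rank ≈ 11–12 of 40.
* `best_rank_attained` (`method="min"`): the raw best rank ever observed
  for the group in the pooled window. Being a minimum it is monotone
  non-increasing in the amount of pooled data and converges to 1
  whenever top-rank occupancy is positive at all, however small — in the
  default regime the L-group's top-rank occupancy is ≈ 2%, so this
  estimator reads 1 on any sizeable pool. It is kept for completeness
  and for degenerate-case reasoning, not as a ceiling locator.

Note the occupancy curve constrains these quantities jointly: summed
over ranks, occupancy equals the group size, so a group holding ~60% of
the bottom half and near-half of the upper-middle ranks *must* appear
occasionally in the top dozen. A literal "never above rank 12" is
arithmetically incompatible with those shares; the ceiling is a
steep-decline feature of the occupancy curve, which is what the default
estimator locates.

## Experiment designs and desk scales

* `baseline_experiment`: one group, all agents at σ_S — the comparison
  baseline for the two-group runs.
* `two_group_sweep`: equal groups over the σ_S grid
  (0.03 … 3, denser at small values where the logistic is steepest) × σ_L
  relations, 50 replicas at full scale; emits group summaries, ranks,
  occupancy, advancement and glass-ceiling tables per cell.
* `group_size_sweep`: group split 0–40 by 5 × σ grid × k ∈ {0..3},
  30 replicas at full scale, uniform pairing; emits top-5/bottom-5
  Z-scores (degenerate one-group cells carry no Z rows).

`SweepConfig.scale_factor` shrinks horizon and replica count
proportionally for desk-scale runs; the snapshot cadence shrinks with
the horizon so each run keeps ≥ 10 snapshots. The test suite runs the
equal-group design at 30–50 replicas × 100k iterations (occupancy and
ceiling measurements; the trailing window is then late-transient rather
than fully stationary, which the acceptance bands absorb), 10 × 500k for
the stationary group comparisons (the sign of the S-group's mean
reputation settles only after a few hundred thousand iterations), and a
3-fraction × 2-gossip size sweep at the design's own 30 replicas — the
bottom-5 over-representation of a small L-minority is a real but modest
effect (a few percentage points of occupancy) that smaller replica
counts under-resolve.

## What the simulations do and do not show

All inputs are synthetic: the generator *is* the model, so passing tests
establish internal reproducibility of the emergent phenomenology
(inter-group reputation/self-esteem gaps, stratification asymmetry,
glass-ceiling rank mobility, size-robust extreme-rank skew), not any
claim about human populations. The two groups differ in exactly one
scalar; real gender differences in status cognition are neither this
clean nor this unidimensional. Contact is uniformly random — no
homophily, networks, roles or institutions — and the esteem scale is an
abstraction with arbitrary units and bounds.

## Numerical and degenerate-case choices

* Clipping to the bounds happens after every single entry update, not
  per interaction.
* With δ = 0 the all-zero state is an exact fixed point (asserted).
* Odd N runs `floor(N/2)` encounters per iteration.
* `n_iterations = 0` yields a series containing only the initial
  snapshot; indicators needing two snapshots raise informative errors.
* Empty groups: aggregates over an empty group raise; occupancy and
  Z-scores for a one-group population are degenerate and are skipped
  (sweeps) or raised (direct calls).
* A replica failure inside a sweep is recorded as a flagged row, never
  silently dropped.

## Known limitations

* The numba kernel compiles on first use (~10 s per process); pass
  `engine="python"` for latency-free tiny runs.
* Pooled-snapshot statistics ignore temporal autocorrelation (see the
  Z-score note); error bars, where needed, should come from
  between-replica dispersion.
* The occupancy-crossing ceiling estimator has a one-to-two-rank
  seed-to-seed spread at 30–50 replicas because occupancy is nearly flat
  just below the ceiling.
* Sweeps execute serially; cells are seed-independent, so external
  parallelisation is safe but not built in.
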