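# Methods

## Model

A binary environment ε_t ∈ {0, 1} (1 = good year) drives an annual-plant
seed bank. A seed carries an internal state s ∈ {0…L−1} (for the *age
diagram*, its dormancy age truncated at L−1). In state s it germinates
with probability q_s; germination yields Y_ε seeds that start in state
`germ_succ(s)` (age 0 for the age diagram), dormancy moves the seed to
`dorm_succ(s)` with viability V. Defaults throughout: Y₀ = 0, Y₁ = 4,
V = 0.9. Stacking states gives the yearly projection
N_t = M(ε_t; q)·N_{t−1}, where column s of M carries q_s·Y_ε into row
`germ_succ(s)` and (1−q_s)·V into row `dorm_succ(s)` — for the age
diagram, a Leslie-type matrix with fertility row q_α·Y_ε, sub-diagonal
(1−q_α)·V and a terminal self-loop. The long-term growth rate Λ is the
Lyapunov exponent of the random matrix product.

The *diagonal* (extreme-selection) fitness variant f = [[V, 0], [0, Y]]
kills dormant seeds in good years; under it the optimal strategy is
proportional betting and the growth-rate hierarchy is exact information
arithmetic: Λ_max = p·lnY + (1−p)·lnV, Λ_bet = Λ_max − H(ε),
Λ_cue = Λ_bet + I(ε; ξ). The implementation computes each level by an
independent route (perfect-foresight average; the Kelly closed form
p·ln(pY) + (1−p)·ln((1−p)V); the per-cue proportional-betting sum), so
the identities are cross-checks rather than tautologies. Under the
general (non-diagonal) matrix these identities are *not* exact and are
not asserted anywhere.

## Environment generator

The default environment alternates runs: good-run durations geometric on
{1, 2, …} with continuation 1−1/5 (mean 5 years); bad-run durations from
a Gaussian (mean 5, sd 2) rejected outside [0, 10], rounded to the
nearest integer, and re-drawn on 0. The rounding/re-draw rule is a
modelling choice (any discretisation preserving the printed mean would
do); enumerating it exactly gives mean 5.0306 — the loss of the k = 0
cell shifts the mean slightly above 5 — and realised sd ≈ 1.94. The
stationary good-year frequency is therefore 5/(5 + 5.0306) ≈ 0.4985.
Sequences start at the beginning of a good run; 1000 burn-in years are
discarded before any stationary statistic (initial-phase bias decays on
the run-length scale, so 10³ years is conservative). An i.i.d.
Bernoulli(p) mode (default p = 0.5) is the no-structure control: it
matches the marginal frequency while destroying all temporal order.

What the generator does *not* emulate: continuous environmental quality,
more than two states, long-memory (non-renewal) correlations, and
observation noise. Tests passing on it show the machinery is correct
under the stated renewal process, not that real climates behave this way.

Information quantities are plug-in block-entropy estimates in nats
(growth rates are nats/year, so Λ and I share an axis; a bits conversion
is provided on `InfoSummary`). Plug-in bias is of order
(#cells)/(2T) nats; tests comparing an estimate to zero allow 3× that
bound.

## Numerics

*Lyapunov exponent.* The population vector is renormalised to unit
1-norm every year and the log factors accumulated — the standard
stabilisation, exact in infinite precision and overflow-free over 10⁶
years. Each diagram column has exactly two non-zeros, so one year costs
O(L); the loop is a numba kernel. The standard error is batch means over
100 equal batches. An exactly zero vector (possible only on the q = 1
boundary with Y₀ = 0) sets Λ = −∞ with an `extinct` flag instead of
raising, so optimisers can traverse the boundary. Defaults: T = 2×10⁵
years with 10³ burn-in for optimisation objectives; lineage statistics
use T = 10⁶. These sizes put the batch-means se (~3×10⁻³ nats/yr) well
below the Λ differences across L that the analyses resolve.

*Optimisation.* The objective uses common random numbers: one fixed
training sequence makes Λ(q) deterministic, and a held-out sequence
(independent seed) gives the reported estimate, so training noise is not
mistaken for signal. q is optimised through a logistic bijection onto
(0, 1) with Nelder-Mead (fatol 10⁻⁶ nats, xatol 2×10⁻³ in logit space,
≤150·L evaluations per start), multi-started from the constant analytic
optimum q*, a warm start where available, and random vectors
(`restarts − 1` of them; default 5 restarts, 2 in the heavier sweep and
search runs). The memory sweep warm-starts L+1 from the L-optimum with
its last entry duplicated; this nesting makes Λ(L) non-decreasing on the
training sequence by construction. Reported q are clipped to
[10⁻⁶, 1−10⁻⁶] so lineage weights stay positive.

*Topology enumeration.* All L^L × L^L successor-map pairs are generated;
each is pruned to the states reachable from germination targets, and
deduplicated by a relabeling-invariant canonical form (lexicographic
minimum of the encoded maps over all state permutations of the pruned
diagram — exhaustive, hence provably invariant; at L ≤ 4 this is at most
24 permutations per diagram). Counts: 1 topology at L = 1, 9 at L = 2,
90 at L = 3. L ≥ 4 grows combinatorially and is flagged long-running.
Because pruning precedes deduplication, a diagram with unreachable states
is identified with its effective smaller topology. Whether a different
search convention (e.g. no reachability pruning) would count topologies
differently is unknowable from the outside; the family here is
documented and self-consistent.

*Lineage sampling.* The selection-weighted sampler draws each year's
phenotype with probability ∝ strategy weight × fitness
(P(germinate) = q_s·f_{ε,1} / (q_s·f_{ε,1} + (1−q_s)·f_{ε,0})), which
reproduces the phenotype statistics of a surviving line of descent;
viability enters through f_{ε,0} = V, so no separate death/resampling
step is needed. With Y₀ = 0 this makes germination in bad years
impossible — exact, not approximate. The neutral sampler uses q_s alone
(no environment), modelling germination assays under constant
conditions.

*Run lengths.* A duration is a maximal block of identical
phenotypes (or years), counted in years; boundary-truncated blocks are
excluded. Under this convention the L = 2 age diagram gives germination
runs geometric with continuation q₀ (mean 1/(1−q₀)) and dormancy runs
geometric with termination q₁ (mean 1/q₁) — both verified against
chain-enumeration oracles in the tests. Geometric goodness of fit uses
the MLE continuation parameter from the sample mean and a chi-square
with upper-tail pooling so every expected bin is ≥ 5, one df deducted
for the estimated parameter; fewer than 30 complete runs flags the
statistics unreliable rather than testing.

## Design choices where the design was open

- **Discretisation of the bad-year law** (rejection → rounding →
  re-draw on 0): chosen for symmetry, so the mean-5 property survives
  discretisation; the realised sd does not, so nothing asserts the sd.
- **Information units**: nats everywhere internally, matching Λ.
- **Exact decomposition only in the diagonal limit**: with V > 0 in good
  years the Kelly identities fail numerically, so they are treated as
  schematic for the general fitness matrix.
- **Ties in the diagram search** are reported as the set of topologies
  within one combined se of the best, not a single winner — Monte-Carlo
  Λ cannot resolve finer differences (at L = 3 several distinct
  topologies tie with the age diagram at the optimum).
- **Pipeline formats**: TOML config in, TSV + JSON sidecars out; no
  established binary format fits this model's data, and plain text keeps
  every output auditable and byte-reproducible.

## Known limitations

- No density dependence, demographic (finite-population) noise, or
  spatial structure: Λ is the deterministic-renewal Lyapunov exponent.
- Strategies combining internal state with external cues are out of
  scope, as are environments with more than two states or non-renewal
  memory.
- Enumeration beyond L = 4 is computationally heavy (L = 6 has
  6¹² ≈ 2×10⁹ raw map pairs) and not exercised by the test suite.
- Optimisation is derivative-free local search with multi-start; for
  L ≤ 10 the landscape is benign in practice (warm starts and restarts
  agree), but global optimality is not guaranteed.
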