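# Methods

## Model representation

A metabolic model is the stoichiometric matrix `S` (N internal metabolites ×
M reactions) with per-reaction reversibility flags and optional target,
biomass and `v_max` annotations.  Exchange reactions are single-ended
columns: the boundary side is implicit, so `S v = 0` expresses steady state
over internal metabolites only.  Before any optimization, reversible
reactions are split into a forward component (original id and column) and a
backward component (`_b` suffix, negated column); the pairing is recorded so
the design MILP can forbid simultaneously up-regulating (or down-regulating)
both directions of the same enzyme.  Splitting preserves the net-flux
polytope — any feasible split flux maps to a feasible net flux via
`v_net = v_fwd − v_bwd` — which the test suite verifies by LP sampling.

## Capacity distributions

An engineering modification multiplies an enzyme level by an uncertain
fold-change, modelled as a normal distribution truncated to
`[μ − δ/2, μ + δ/2]` and renormalized, with the spread defined as
`δ = 6σ`.  Defaults: up-regulation `μ = 6, δ = 8` (support `[2, 10]`),
down-regulation `μ = 0.5, δ = 1` (support `[0, 1]`).  The up-support is
required to satisfy `μ − δ/2 > 1` so up-regulation always raises the
capacity above the unmodified state.

Truncation is a deliberate design choice: the worst-case (ε = 0) design
needs a finite distribution minimum to be meaningful, and the constraint
`μ − δ/2 > 1` on the spread only makes sense for a bounded support.  An
unbounded normal would make the worst-case bound −∞ and the ε = 0 quantile
undefined.

Two routes produce per-reaction capacity distributions:

* **Kinetic route** (`capacity.kinetic_capacity`): when `v_max` is known,
  the capacity is the fold-change distribution scaled by `v_max` — a
  truncated normal with location `v_max·μ`, scale `v_max·δ/6` and support
  `v_max·[μ − δ/2, μ + δ/2]`.  Scaling commutes with quantiles, which the
  suite checks quantile-by-quantile.
* **EM/ECF route** (`em_ecf`): for stoichiometric models without kinetic
  data, described below.  It yields *empirical* distributions (a sample of
  capacity values) with quantiles by linear interpolation of the order
  statistics, endpoints pinned to the sample min/max so the ε = 0 quantile
  is the observed worst case.  A configurable floor (default 100) rejects
  samples too small to use in optimization.

Missing `v_max` values are completed by LP (`capacity.complete_vmax`): the
unknown `v_max_j` is the maximal flux of `j` subject to steady state and the
known caps; an unbounded LP means the known set cannot bound that flux and
is reported as an error rather than silently capped.

Reference-state bounds (`capacity.estimate_reference_state`) come from
flux-variability LPs: `SSU_j`/`SSL_j` are the max/min of `v_j` over
`{S v = 0, 0 ≤ v ≤ v_max, v_k = measured_k}`.  The measurement equality can
be relaxed to a relative band (`measurement_tol`, default 0) because real
exchange measurements need not be exactly consistent with `S v = 0`.  The
wild-type maximal biomass flux is computed *without* the measurement
constraints — the viability constraint of the optimizers references the
theoretical maximum of the unmodified network, not the observed state.

## The design MILP

Variables: fluxes `v ≥ 0` and binaries `y_j^u`, `y_j^d` for the eligible
reactions (those with a capacity distribution for the relevant direction;
target and biomass are excluded from down-regulation by default).
Objective: `max v_target − α Σ(y^u + y^d)`.  Constraints: steady state;
minimal biomass (fraction of the wild-type maximum, default 1%, skipped when
the model has no biomass reaction); the capacity bound
`v_j ≤ SSU_j + y_j^u (Q_j^u − SSU_j) + y_j^d (Q_j^d − SSU_j)`; the lower
bound `v_j ≥ SSL_j (1 − y_j^d)`; the cardinality cap `L`; per-reaction
up/down exclusivity; and the split-pair rule exactly as stated (no pair may
be both-up or both-down; up on the forward with down on the backward is not
forbidden).

`Q_j` is the ε-quantile of the capacity distribution (CCOpt), its support
minimum (DetOpt ≡ ε = 0), or a Monte-Carlo draw (MCOpt).  Down-regulation
quantiles and draws are capped at `SSU_j` in all three solvers: lowering an
enzyme level must not raise the capacity above the unmodified state, and a
wide down-distribution could otherwise place probability mass above `SSU`.

Numerical choices: LPs and MILPs are solved with HiGHS (scipy ≥ 1.9);
integrality tolerance 1e-6, with binaries rounded and the combinatorial
constraints re-verified post-solve; the flux vector is then recomputed by an
LP with the binaries fixed, so reported fluxes satisfy `S v = 0` to LP
tolerance rather than MILP slack.  LP values below 1e-9 are reported as
exact zeros because SSU/SSL feed MILP bounds downstream.

The penalty `α` defaults to `1e-4 ×` the wild-type target optimum (or 1
when that optimum is 0).  It exists to break ties toward smaller
intervention sets; users should keep `α·L` below the smallest flux
improvement they care about.  Tie-breaking among equally-optimal sets is
solver-dependent, so tests compare objectives unless a fixture has a
provably unique optimum.

## Monte-Carlo optimization and evaluation

**MCOpt** draws one capacity per eligible (reaction, direction), solves the
deterministic MILP, and repeats.  One master seed spawns independent
per-sample substreams (`numpy.random.SeedSequence`); within a sample, draws
are ordered by (reaction id, direction), so results are reproducible and
independent of iteration order.  Per-sample infeasibility is recorded under
a sentinel key in the frequency table, never fatal.

**MCEval** fixes an intervention set and repeatedly solves plain FBA with
the intervened capacities drawn (down-draws capped at `SSU`), unmodified
reactions at `[SSL, SSU]`, down-regulated lower bounds at 0, and the
biomass floor enforced.  Infeasible samples are counted and excluded from
the percentiles — silently dropping them would bias the summary invisibly.

Percentiles use the operational below/above-count definition rather than
interpolation: the 5th percentile is the smallest sample value with at
least 5% of the data at or below it, the 95th the largest with at least 5%
at or above it.  This makes degenerate outputs exact — a point-mass
distribution reports identical 5th and 95th percentiles — which an
interpolating rule would blur.  Default 10,000 evaluation samples, chosen
for percentile stability of roughly ±1 percentile point.

## Elementary modes and ECF

Elementary modes of the split network (`{S v = 0, v ≥ 0}`) are enumerated
by iterative double description on the irreversible flux cone: process one
steady-state row at a time, keep rays on the hyperplane, and combine
adjacent positive/negative ray pairs, with the standard adjacency test (a
pair combines only if no third ray's support is contained in the union of
theirs).  Futile two-cycles supported exactly on a forward/backward split
pair are filtered afterwards; modes are normalized to max entry 1 (mode
coefficients absorb scale, and normalization makes deduplication
deterministic), deduplicated, and ordered lexicographically by support.  A
configurable cap (default 10^6) aborts enumeration on networks too large
for exact EM analysis, which is practical only below roughly a hundred
reactions.

ECF capacity estimation proceeds in four steps: (1) enumerate the modes;
(2) constrain the mode coefficients `λ ≥ 0` to reproduce the reference
state (`SSL ≤ Eλ ≤ SSU`, equalities at measured reactions) — generally an
underdetermined polytope, not a point; (3) model an enzyme modification by
scaling `λ_k → λ_k · f^h` for every mode `k` whose support contains the
modified reaction (`f` the fold-change, `h` the power-law exponent,
default 1 and configurable since no canonical value is fixed by the
procedure); (4) take the LP maximum of the modified reaction's
reconstructed flux over the polytope as its capacity.  Repeating step 3–4
over fold-changes drawn from the fold-change distribution yields the
empirical capacity distribution, one reaction at a time.

The coefficient-estimation step is deliberately an LP over the polytope
rather than an iterative update scheme: the ECF problem is underdetermined
and its answer is a range of minimal and maximal flux, and the LP computes
that range exactly and reproducibly.  This is the package's own resolution
of a step for which no unambiguous iterative specification exists; it
satisfies the checkable properties (identity at fold-change 1, linear
scaling on single-mode networks, monotonicity in the fold-change, recovery
of `SSU` at a unit point mass), all of which are under test.

## Synthetic fixtures and the oracle

The fixture generator builds small irreversible networks with *planted*
bottlenecks whose optimal designs are known by construction:

* **linear** (`make_linear_fixture`): an uptake → conversions → export
  chain, reference ceiling 30 flux units, one interior bottleneck at
  `SSU = v_max = 5`.  The wild-type optimum is the bottleneck bound; the
  unique optimal single intervention is up-regulating the bottleneck.  The
  3-reaction instance is the canonical example in the README and tests.
* **branched** (`make_branched_fixture`): one uptake feeding competing
  export branches, with *two serial* bottleneck reactions on the target
  branch — no single intervention helps (the unchanged serial partner
  inherits the limit), so `L = 1` optimally selects nothing and `L = 2`
  must select both.  Competing branches carry down-capacity distributions
  but have reference lower bounds of zero, so down-regulating them is never
  selected: the optimizer's choices depend on the observed reference state,
  not just the topology.
* **randomized** (`make_random_fixture`): either topology with magnitudes
  jittered from a seed (ceiling uniform in [20, 40], bottleneck in [2, 8]),
  for property tests.

The values 30/5 (and the jitter ranges) keep the two regimes well separated:
the median up-fold-change (6×) exactly saturates the chain ceiling while the
worst case (2×) does not, so worst-case and chance-constrained designs
predict visibly different fluxes at identical intervention sets.

`brute_force_optimum` is the independent oracle: it enumerates every valid
intervention set of size ≤ L (guarded at 12 eligible reactions and L ≤ 3),
fixes bounds by direct substitution of the ε-quantiles, solves each LP, and
returns the best penalized objective — no MILP machinery involved.  Solver
and oracle agree to 1e-6 across 20 seeded fixtures × 4 confidence levels ×
L ∈ {1, 2} in the acceptance suite.

What the fixtures do *not* emulate: realistic network sizes, biomass
composition, cofactor coupling, correlated capacities across reactions
(independence is assumed throughout), or measurement noise.  Passing tests
demonstrate the correctness of the optimization, sampling and enumeration
machinery on exactly solvable instances, not biological predictive power on
real models.

## Problem sizes and defaults used in the shipped analyses

The acceptance script and tests use: 20 random fixtures for oracle
comparison; 1,000 Monte-Carlo optimizations for modal-set frequencies;
10,000 Monte-Carlo evaluations for percentile summaries and the
Kolmogorov–Smirnov comparison against the analytic push-forward (bound
0.02, with the atom at the chain ceiling handled by comparing ECDF and CDF
left/right limits at distinct values); 500 ECF draws for the empirical
capacity example.  These sizes give Monte-Carlo summaries stable to well
within the asserted tolerances while keeping the full pipeline quick on a
single CPU.

## Package shape

The library exposes both the functional surface (`ccopt_solve`,
`mcopt_run`, `mceval_run`, …) and a statsmodels-flavoured wrapper
(`StrainDesign.fit()` returning `StrainDesignResults` with `summary()` and
`evaluate()`), plus a thin `strainopt` CLI over the same functions.  A
further known limitation: the MILP returns a single optimum — alternate
optima are not enumerated, and tie-breaking among them is solver-dependent.
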