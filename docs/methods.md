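# Methods

## Model

A flow network is treated as a steady-state budget: an `(S+2) × (S+2)`
nonnegative flux matrix with a source (index 0) that only emits and a sink
(index S+1) that only absorbs. Self-loops (cannibalism) are permitted.
Steady state means inflow equals outflow at every living compartment; the
per-node residual relative to throughflow is the balance measure
(`check_balance`), with denominator `max(inflow, outflow, 1e-30)` so that a
node with flow on only one side is always flagged.

The analysis is donor-normalized: `m_ij = f_ij / A_i` is the probability
that a unit of flux leaving `i` goes next to `j`, and the one-step
absorption probability into the sink is the row-sum deficit. This
orientation is forced by the particle picture — energy moves downstream from
source to sink — and is the standard output-oriented convention of
ecological network analysis. The source is not a state of the chain;
whole-network walks would be injected at living nodes in proportion to the
source fluxes.

The fundamental matrix is obtained by solving `(I − M) N = I` (LU solve, not
an explicit inverse). Before solving, the spectral radius of `M` is checked:
a value at or above 1 means some compartment cannot reach the sink
(non-dissipative component) and the analysis refuses to continue; a
condition number of `I − M` beyond `1/eps` is likewise rejected.

Two impact variants are provided because the expected-visits algebra is
ambiguous on cyclic networks:

- `expected_flux` (default): `C_i = A_i Σ_j n_ij`. Every pass of a particle
  through a cycle counts again. This is a closed-form matrix product and
  reduces exactly to the subtree flow sums on trees.
- `labeled_particles`: `C_i = (A_i / n_ii) Σ_j n_ij`. Dividing by the
  expected number of visits to the start node converts visit counts into
  counts of *distinct* particles that ever passed `i`. The two coincide
  whenever `n_ii = 1`, i.e. on all acyclic networks.

Self-loops are kept in `M`; they inflate `n_ii`, which is exactly the case
the second variant corrects for.

## Balancing

Empirical budgets are rarely exactly balanced, and the Markov construction
requires balance. Four strategies are implemented behind one interface
(`balance(net, method)`), all post-checked at relative tolerance 1e-9:

- `naive` — surplus inflow is dumped onto the node's sink edge, deficits are
  drawn from the source. Touches only boundary edges; exact in one pass.
- `input` — inputs are authoritative. Keeping the source row and every
  node's outflow *proportions* fixed, the implied throughflow satisfies the
  linear system `A = s + P^T A`; the outflow rows are then rescaled. Exact.
  Fails (by design) when a node has inflow but zero outflow.
- `output` — mirror image: sink column and inflow proportions fixed,
  `B = d + Q B` solved, inflow columns rescaled.
- `average` (default) — symmetric compromise: each iteration pulls every
  node toward the mean of its inflow and outflow by multiplying living rows
  by `sqrt(target/outflow)` and living columns by `sqrt(target/inflow)`
  (Sinkhorn-style two-sided scaling). Balanced networks are a fixed point;
  convergence is linear in practice and capped at 1e5 iterations.

`average` is the default because it distorts both sides minimally and
requires no authority choice. Dissipation for the γ fit is always read from
the pre-balancing matrix, so `balance` never mutates its input.

## Scaling fits

Both exponents are ordinary least squares on `log10` pairs, base 10 fixed so
intercepts are reproducible; the slope is base-independent. `r_squared` is
the squared Pearson correlation of the log pairs. Pairs with a nonpositive
coordinate are excluded and counted (`excluded`) — for the dissipation law
this implements the convention that zero-dissipation nodes simply vanish
from log axes rather than being imputed. Ties are kept; the regression is
unweighted; source and sink never enter a fit.

A fit needs at least two surviving pairs (two points determine a slope with
a trivially perfect r²; the exactly solvable two-node chain used as an oracle
depends on this). `ScalingFit.n_points` is reported so callers can impose a
stricter reportability threshold (three or more points is sensible for real
data). A fit with zero variance in `log10 x` is an error; zero variance in
`log10 y` returns slope 0 with r² = 1 (an exact horizontal law, e.g. unit
consumption on a Banavar tree).

## Flow Adjusting Algorithm

Given a balanced, source-connected network and a target law `d = c·A^β`, the
FAA iterates a worklist: pop node `i`, read its current outflow to living
nodes `o_i`, solve the scalar equation `x = o_i + c·x^β` for the new influx,
rescale all incoming edges of `i` by a common factor (which preserves influx
ratios exactly), and set `f_{i,sink} = c·x^β`. Any change above `root_tol`
pushes `i`'s living upstream neighbours. The worklist starts at the nodes
adjacent to the sink — the only ones whose equation inputs are immediately
meaningful — and propagates upstream; source edges are rescaled implicitly
when basal nodes are processed. Between sweeps the order can be shuffled
under a seed to break cycles of updates.

Scalar solve: for β < 1 the positive root is unique (bracketed Brent plus a
Newton polish to machine precision, so the restored balance is exact to
~1e-15 relative). For β = 1 the equation is linear and requires `c < 1` and
a positive living outflow — a terminal node (sink-only outflow) at β = 1 is
declared infeasible, matching the mathematics. For β > 1 there may be zero,
one or two positive roots; the smallest is returned and a missing root
raises "dissipation target infeasible".

Convergence is judged on the *global* refit: the adjusted network's fitted
dissipation exponent within `beta_tol` (default 0.01) of β, its r² at least
`r2_min` (default 0.99), and the balance residual below 1e-6. Runs that
oscillate (residual minima not improving across two 20-sweep windows) or
exhaust `max_sweeps` (default 500) return `converged=False` with the sweep
history instead of raising. A `damping` factor in (0, 1] mixes the old
influx into each update for oscillation-prone topologies.

When `c` is not given it is fitted from the original network as
`10^mean(log10 d − β log10 A)` over positive-dissipation nodes — the
least-squares intercept at fixed slope, which keeps the adjusted network
near the original scale.

Feasibility boundary worth knowing: for β > 1 a terminal node's influx
solves to `c^{1/(1−β)}`, which is simultaneously the *maximum* throughflow
any node can carry under the law (`d ≤ A` forces `A ≤ c^{1/(1−β)}`). Any
node upstream of a terminal node must carry more than the demand it feeds,
so topologies with terminal nodes (niche webs, whose top predators have no
living outflow) are structurally infeasible at β ≥ 1 for any prefactor.
Empirical webs escape this because detritus compartments give essentially
every species a living outflow. Sweeps therefore report a converged
fraction per target and aggregate over converged runs only.

## Generators and null models

- `banavar_flow(tree)` turns a rooted tree into an exactly balanced supply
  network: each node consumes a fixed amount (default 1 unit per time step),
  edges carry subtree consumption sums, the source feeds the root. Chain and
  star trees give closed-form allometric slopes that bracket the tree regime
  (chain → 2 from below, star → 1 from above) and serve as analytic oracles.
- `niche_web` draws the standard one-dimensional niche model: niche value
  `n_i ~ U(0,1)`, diet-range fraction `x ~ Beta(1, 1/(2C) − 1)` so the
  expected connectance is `C`, diet centre `~ U(r_i/2, n_i)`. The
  smallest-niche species is forced basal; duplicate niche values and webs
  with species unreachable from the source are redrawn (bounded retries).
  Edges are oriented prey → predator; basal species hang off the source and
  every species is attached to the sink.
- `assign_random_flows` draws `U(0, f_max]` per edge (half-open so no edge
  is deleted); the result is intentionally unbalanced, callers balance it.
- Null models (`rewire_random_weights`, `topology_random_weights`,
  `shuffle_weights`) keep node and edge counts; the rewire mode forbids
  multi-edges but allows self-loops (present in real webs). Null outputs are
  never balanced automatically: dissipation is read raw (unbalanced nodes
  then drop from the γ fit via zero/exclusion), and a copy is balanced —
  `naive` is the robust choice there, since rewiring creates nodes with
  one-sided flow — before the allometric fit.

What the synthetic webs emulate: sizes (tens of compartments), connectances
(0.1–0.4), flows spanning orders of magnitude after balancing, cycles, and
sub-linear dissipation once imposed by the FAA. What they do not emulate:
empirical flux distributions (real webs are far more skewed than uniform),
detritus recycling loops (hence the β ≥ 1 infeasibility above), and
measurement noise. Passing tests on them validates the algebra and the
algorithms, not ecological conclusions about any particular web.

## Problem sizes and tolerances in the test suite

The suite is sized for a single CPU: the random-walk oracle uses 2×10^5
walkers per start node on 50 niche webs of 12 species (the 3-standard-error
criterion is asserted as ≥ 99% of matrix entries, consistent with 3σ
coverage of 99.7% over ~7000 entries); parameter recovery runs 50 webs of 50
species over eight targets; balancing properties use 250 random webs per
method. Balance tolerances: 1e-9 post-balancing, 1e-6 as the analysis
precondition, machine-level for the FAA's restored balance.

## Known limitations

- Storage-based (biomass-stock) network analysis, ascendency/information
  indices and utility analysis are out of scope.
- The empirical-web comparison requires the public Pajek files, which are
  not redistributed; without them that check reports what is missing.
- `rewire_random_weights` does not preserve degree sequences (deliberately:
  it is the harshest structural null).
- The FAA solves the law node-by-node rather than as one nonlinear system;
  this is the intended approximate scheme, and on some random topologies it
  oscillates — reported honestly via `converged=False` diagnostics.
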