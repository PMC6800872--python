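# Methods

## Model

Somata are a Poisson point process of intensity μ on Λ = [−w, w]².  Each
soma v grows an axonal tree **T**_v(t) by a planar branching random walk:

* the root ray starts at v at time 0 in a Uniform[0, 2π) direction and
  elongates at speed 1 (speed is a time rescaling, so it is fixed);
* every living ray carries an independent Exp(λ) lifetime; when it expires
  the ray stops and two child rays start at its tip, **each** drawing its
  direction as parent direction + Uniform[−α, α] independently (neither
  child inherits the parent direction deterministically);
* growth stops at the horizon t_max; λ = 0 yields a single ray and is
  handled without drawing any exponential clock.

Trees may self-intersect and grow freely beyond Λ; no stopping or
reflection at the boundary is modelled.  Dendrites are collapsed into a
disc of radius r around each soma.  A directed edge v → u is present at
time t iff the Euclidean distance from **T**_v(t) to u is at most r; its
formation time is the first such t.  Edges out of one soma are dependent
(one shared tree); edges out of distinct somata are independent given the
positions.

### Parameters

| symbol | meaning | units | typical values here |
|---|---|---|---|
| λ  | branching rate | 1/time | 0–10 |
| α  | maximal deviation of a child ray | rad, in [0, π] | π/6, π/2, π |
| μ  | soma intensity | 1/area | 10–100 |
| r  | soma + dendrite disc radius | length | 0.01–0.1 |
| w  | half-width of Λ | length | 0.1–1.2 |
| t  | developmental time (= length grown) | time | 0–3 |

The asymptotic degree analysis assumes the thin-axon scaling w = Θ(1),
r = o(1), μ ≫ 1, μr = o(1); experiment configs warn (but do not fail) when
parameters leave it, because the simulation itself stays exact.

## Exact geometry

Everything is computed segment-wise in closed form, never on a time grid:

* **first contact**: a ray from x₀ toward a target at distance d with
  angular offset φ enters the disc of radius r after arc length
  s₀ = d·cosφ − sqrt(r² − d² sin²φ), provided cosφ > 0 and |d sinφ| ≤ r;
  the edge time is the minimum over segments of birth time + s₀, with a
  segment start already inside the disc contributing its birth time.  Ties
  between segments are resolved by the minimum (they have measure zero).
* **clipped length**: segments are intersected with axis-aligned rectangles
  by Liang–Barsky interval clipping, so clipped lengths over a partition of
  the plane sum exactly to the total length.

With λ = 0 each arbor is a single ray and the full pairwise edge matrix is
vectorised; the generic per-arbor path produces bit-identical graphs
because every arbor draws from a substream derived deterministically from
the master seed and its node index (this also makes graphs independent of
evaluation order).

## Connection probability

For a single ray (λ = 0) the probability that v connects to a target at
distance d > r by time t is piecewise:

* 0 for t < d − r;
* arccos((d² + t² − r²)/(2td))/π on the transition interval;
* arcsin(r/d)/π (saturation) for t > sqrt(d² − r²).

The transition branch has square-root onset at t = d − r, which amplifies
rounding to ~sqrt(machine eps); the breakpoint itself is therefore assigned
to the zero branch (the identical limiting value, exactly).

For branching growth with full angular randomisation (α = π) the
no-connection probability q(t, d) satisfies a Volterra-type integral
equation obtained by conditioning on the first split: a split at time s
before the root ray would have touched the disc (s < s₀(φ) when the ray
aims at it, any s ≤ t otherwise) leaves two independent subtrees at
distance d̃(d, s, φ) = sqrt(d² + s² − 2ds·cosφ), contributing q(t−s, d̃)²;
no split contributes e^{−λt}·q₀(t, d).  The solver (`solve_q_pi`)
time-marches this equation:

* uniform t grid; the s quadrature reuses the same grid (trapezoid), with
  the s₀ cutoff handled by a left-rectangle partial cell;
* trapezoid in φ with `n_phi` nodes per symmetric half-sector (the sector
  widths vary with d, so nodes are scaled per distance);
* q(t−s, d̃) is linearly interpolated in d; any off-grid state with
  t−s ≤ d̃ − r is exactly 1 (the subtree cannot reach the disc), which also
  covers d̃ beyond the grid whenever the d grid extends to t_max + r —
  recommended and used by all callers;
* the s = 0 endpoint couples the layer to itself; since d̃(d, 0, φ) = d the
  coupling is a scalar quadratic per distance node, resolved by fixed-point
  sweeps to sup-change < 1e-6 (2–3 sweeps in practice);
* values are clipped to [0, 1] and states with t ≤ d − r pinned to 1.

At λ = 0 the branching integrands carry a factor λe^{−λs} = 0, so the
closed form *is* the solution and is returned without quadrature.  The
quadrature path is validated against the branching-tree simulator (10⁵
replicates, agreement within 3 binomial SEs at all probes) and by
self-convergence under step halving (sup-norm ≈ 3e-4 on the default grid).

## Degree laws

For an interior soma (|x|, |y| < w/2 and t < w/2, so the r-neighbourhood of
its tree stays in Λ), the out-degree is Poisson(μ·|A_r(T_v(t))|).  With
λ = 0 the neighbourhood is a stadium of exact area 2rt + πr², so the
out-degree is exactly Poisson((2rt + πr²)μ); the in-degree is exactly
Poisson with mean given by the radial integral ∫ 2xμ·arcsin(r/x) dx from r
to sqrt(t² + r²) (leading order 2μrt; the integral value, not the leading
order, is used as the χ² reference).  The hub diagnostic operationalises
the order relations "x ≪ y" as x ≤ y/10 and "Θ(1)" as a ratio in [1/10,
10]: with λ = 0 the max degree vanishes when μ²rt ≤ 0.1 and hubs require
μ²rt ≥ 10 with μrt ≤ 0.1; with λ > 0 the driver is μ·r·e^{λt}.

A subtlety found while testing: the no-branching network is *not* exactly
frozen after t = 2w (straight axons can make a first contact as late as the
region diagonal 2·sqrt(2)·w plus r); it is frozen after that diagonal time,
and ≥95% of final edges are typically present by 2w.  Statements about
freezing at 2w should be read as order-of-magnitude.

## Network statistics and the null model

* Average shortest path: hop counts; unreachable ordered pairs contribute
  distance 0 (this deflates averages on sparse graphs but keeps the
  statistic defined everywhere; `reachable_only=True` is available for
  sensitivity analysis).
* Directed clustering: Fagiolo's construction; per node,
  t_v = ((A+Aᵀ)³)_vv / 2 divided by k_v(k_v−1) − 2·(A²)_vv with k_v the
  total degree; nodes with non-positive denominator contribute 0 and stay
  in the averaging count, so the coefficient is defined for every graph.
* Null model: directed G(n, m) matched exactly on the snapshot's node and
  edge counts, sampled uniformly without replacement over ordered pairs.

## Degree fitting

Candidates: normal, Poisson, exponential, gamma, lognormal.  Counts are
fitted with continuous densities directly (no continuity correction) —
the comparison mirrors standard practice of asking which textbook family
summarises a degree histogram.  Normal σ uses the 1/n MLE so AIC = 2k −
2·log L holds exactly; standard errors come from the observed information
(closed forms; the gamma information matrix is
n·[[ψ′(a), 1/θ], [1/θ, a/θ²]]).  Zeros: exponential is allowed (finite
density at 0); gamma and lognormal are reported unavailable.  Ties in AIC
break toward fewer parameters, then a fixed family order.

## Experiments: conventions and sizes

The intensity convention follows the time-resolved studies, which fix
μ/w² — "the intensity of the nodes per unit area" — while varying w, so the
expected soma count is 4μ for every width.  This is exposed as
`intensity_mode="scaled"`; plain per-area intensity (`"area"`) and a fixed
count (`"fixed"`) are also available, because the studies are not fully
explicit about the convention in every figure.

Defaults (all overridable):

* **frequency**: λ ∈ {0, 5, 10}, α = π/2, r = 0.01, μ = 100 scaled,
  w = 0.1, probe times t ∈ [w, 3w] (with w = 0.1 this window coincides with
  [√μ·r, 3√μ·r]), 30 replicates.  One graph per replicate is grown to the
  last probe time and snapshotted, so P(t) curves share realisations.  The
  companion width-scan preset uses reduced widths: the ray count grows as
  e^{λt}, and t = 3w at λ = 5 with w ≥ 1 is computationally out of reach
  (a guard raises rather than thrash memory).
* **ratio**: λ = 1, α ∈ {π/6, π}, r = 0.1, w = 1, μ = 10 scaled (≈40
  somata), t ∈ {1, 1.25, 1.5, 1.75, 2}, 30 replicates; each snapshot is
  paired with a fresh matched G(n, m); edgeless replicates are recorded as
  missing, never dropped silently.
* **clustering**: full λ × α × t × w grid with r = 0.1, μ = 10 scaled, 50
  paired replicates per cell; Welch's t-test at the 5% level flags cells
  (Mann–Whitney available by config switch — the original analysis does not
  name its test).
* **degree**: α = π/2, λ = 1.5, μ = 100 per area, w = 1, t = 1.5.  r is
  not stated in the source study; r = 0.01 is used because the realised
  mean degree (boundary truncation included — at t = 1.5 > w/2 roughly half
  of each tree lies outside Λ) then matches the reported common sample mean
  ≈ 5.6, whereas the interior-node formula alone would suggest r ≈ 0.005.
* **corner**: α = π (required: the quadrant argument needs radial
  symmetry), λ = 1, t = 0.5 ≤ w = 1, 10⁴ trees per root position.  The
  out-degree expectation of a soma is μ·E|A_r(T) ∩ Λ| ≈ 2rμ·E[length in
  Λ], so the centre/corner factor is estimated as a ratio of mean clipped
  lengths with a delta-method CI; the analytic values are 4 (corner) and 2
  (edge midpoint).

Every experiment is bit-reproducible from (config, seed); outputs are CSVs
plus a JSON manifest recording the full config, seed and package version.

## What the simulations do and do not show

The generator realises the model's own assumptions: Poisson somata,
independent trees, unit speed, disc dendrites.  Passing tests show internal
consistency (simulation ↔ analytic laws ↔ solver) and the qualitative
regime behaviour (frozen vs linearly growing connectivity, clustering
monotonicity, heavy out-degree tails, hub formation).  They do not show
anything about real neuronal tissue: axons are not straight-speed random
walks, dendritic fields are not discs, somata are not spatially Poisson,
and only *potential* synapses are modelled — no pruning, plasticity or
functional connectivity.  Boundary scenarios (stopping or reflecting at
∂Λ), three-dimensional growth and dendritic arborisation are out of scope.

## Numerical choices and limitations

* Contact times, lengths and clippings are exact per segment (float
  arithmetic only); snapshots are filters on one timed edge list, so t = 0
  is edgeless by convention even when a target starts inside a soma disc
  (such edges carry formation time 0 and exist for every t > 0).
* The solver is restricted to α = π (the equation is derived under full
  angular randomisation) and to uniform time grids; accuracy at the default
  grid (Δt = Δd = 0.01, 48 φ-nodes per half-sector) is a few 1e-4 absolute.
* Monte-Carlo sizes in tests are chosen so checks run in minutes on one
  CPU: 10⁴–10⁵ trees for probability and length laws, 30–100 seeds for
  trend and goodness-of-fit rates; all thresholds (3 SEs, χ² at 1%, 95%
  pass rates) are stated in the tests themselves.
* The ray count grows as e^{λt}; `grow_arbor` refuses (with a clear error)
  trees beyond `max_segments` = 10⁶ rather than exhausting memory.
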