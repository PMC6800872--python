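# arbornet

Networks of randomly grown axonal arbors as a model of potential neuronal
connectivity.

Neurons communicate through synapses, which require physical proximity
between one cell's axon and another cell's dendrites.  `arbornet` implements
a planar stochastic-geometry model of that proximity structure: somata form
a Poisson point process of intensity μ on the square Λ = [−w, w]², and each
soma v grows an independent axonal tree **T**_v(t) as a branching random
walk — a ray elongating at unit speed that splits at Exp(λ) times into two
rays whose directions deviate from the parent's by independent
Uniform[−α, α] angles.  Dendrites (plus soma) are reduced to a disc of
radius r.  A directed *potential synapse* v → u exists at time t when

    ρ(u, T_v(t)) ≤ r,

i.e. when v's tree has come within r of u's soma.  The result is a
time-indexed directed graph G(t) whose edges carry exact formation times —
a spatial random graph with dependent edges (all edges out of v share one
tree), which classical models such as Erdős–Rényi graphs cannot capture.

The package provides:

* **exact simulation** — event-driven tree growth and closed-form
  per-segment first-contact times, so snapshots G(t) involve no time
  discretisation (`arbor`, `spatial_graph`);
* **analytic laws** — the piecewise closed-form single-ray connection
  probability p₀(t, d), expected tree length (e^{λt} − 1)/λ, Poisson in/out
  degree laws for λ = 0, a hub-regime diagnostic, and a time-marching solver
  for the Volterra-type integral equation satisfied by the no-connection
  probability q_{λ,π}(t, d) under full angular randomisation (`analytic`);
* **directed network statistics** — connection frequency, directed average
  shortest path, Fagiolo-style directed clustering, maximal degrees, and a
  matched directed G(n, m) null model (`netstats`);
* **degree fitting** — maximum-likelihood fits of normal / Poisson /
  exponential / gamma / lognormal families to degree samples with AIC model
  selection (`degree_fit`);
* **reproducible studies** — config-driven experiments for the frequency,
  shortest-path-ratio, clustering, degree and boundary (corner) analyses,
  each bit-reproducible from a seed (`experiments`), plus an `arbornet` CLI.

## Worked example

Grow one network with the degree-study parameters (α = π/2, λ = 1.5,
μ = 100, w = 1, r = 0.01, horizon t = 1.5) and compare it with its matched
null model:

```python
import math
import numpy as np
import arbornet as an

rng = np.random.default_rng(0)
field = an.sample_neurons(w=1.0, mu=100.0, rng=rng)
growth = an.GrowthParams(branch_rate=1.5, max_deviation=math.pi / 2, t_max=1.5)
graph = an.build_graph(field, growth, r=0.01, rng=rng)

snap = an.snapshot(graph, 1.5)
null = an.sample_gnm(snap.n, snap.m, rng)
print(f"n = {snap.n} neurons, m = {snap.m} potential synapses at t = 1.5")
print(f"connection frequency P(t)   : {an.connection_frequency(snap):.4f}")
print(f"avg shortest path  G(t)     : {an.avg_shortest_path(snap):.3f}")
print(f"avg shortest path  G(n,m)   : {an.avg_shortest_path(null):.3f}")
print(f"clustering         G(t)     : {an.clustering_coefficient(snap):.4f}")
print(f"clustering         G(n,m)   : {an.clustering_coefficient(null):.4f}")
print(f"max out-degree G(t) vs null : {snap.out_degrees.max()} vs {null.sum(axis=1).max()}")
best = an.select_aic(an.fit_candidates(snap.out_degrees))
print(f"out-degree best AIC family  : {best.family}, params {best.params}")
```

Output:

```
n = 408 neurons, m = 2420 potential synapses at t = 1.5
connection frequency P(t)   : 0.0146
avg shortest path  G(t)     : 2.874
avg shortest path  G(n,m)   : 3.554
clustering         G(t)     : 0.0469
clustering         G(n,m)   : 0.0145
max out-degree G(t) vs null : 45 vs 14
out-degree best AIC family  : exponential, params {'rate': 0.16859504132231404}
```

Reading the numbers: about 1.5% of ordered neuron pairs are potentially
connected; the growing network is three times more clustered than an
edge-matched random graph, its out-degree tail is far heavier (maximum 45
vs 14 — a few somata whose trees sweep unusually long paths act as hubs),
and AIC attributes the out-degree histogram to an exponential rather than
the Poisson shape a classical random graph would show.  All of this comes
from the shared-tree dependence of the out-edges; the *in*-degrees, sums of
independent Bernoulli indicators, stay Poisson-like.

The same pipeline is available from the shell:

```bash
arbornet simulate --lambda 1.5 --alpha 1.5708 --mu 100 --r 0.01 --w 1 \
    --t-max 1.5 --seed 0 --out-dir out/
arbornet stats --edges out/edges.csv --nodes out/nodes.csv --t 0.5 --t 1.0 --t 1.5
arbornet solve-q --lambda 1 --r 0.05 --t-max 1 --out q.csv
arbornet run-experiment --name clustering --seed 0 --out-dir out/clustering/
```

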