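"""Poisson soma fields and the time-stamped directed potential-synapse graph.

Somata are scattered as a Poisson point process on the square
``[-w, w] x [-w, w]``.  Each soma grows an independent axonal arbor; a
directed edge v -> u exists at time ``t`` when v's tree has come within
``r`` of u's soma centre by then.  Edge formation times are computed
analytically per segment (no time discretisation), so any snapshot G(t) is
an exact filter on one edge list.

Reproducibility contract: the caller supplies one seeded generator; each
arbor draws from a deterministically derived substream keyed by its node
index, so the graph is identical regardless of evaluation order, and the
no-branching fast path produces bit-identical edges to the generic path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .arbor import Arbor, GrowthParams, first_contact_times, grow_arbor

__all__ = [
    "NeuronField",
    "ConnectivityGraph",
    "Snapshot",
    "sample_neurons",
    "build_graph",
    "snapshot",
    "estimate_connection_probability",
]

_TWO_PI = 2.0 * math.pi


@dataclass
class NeuronField:
    """Soma positions on the square region of half-width ``w``."""

    half_width: float
    intensity: float | None  # None when the node count was fixed directly
    positions: np.ndarray  # (n, 2), all inside the square

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size and np.max(np.abs(self.positions)) > self.half_width:
            raise ValueError("positions must lie inside [-w, w]^2")

    @property
    def n(self) -> int:
        return 0 if self.positions.size == 0 else self.positions.shape[0]

    def interior_mask(self) -> np.ndarray:
        """Nodes with |x| < w/2 and |y| < w/2 (away from boundary effects)."""
        half = self.half_width / 2.0
        return (np.abs(self.positions[:, 0]) < half) & (
            np.abs(self.positions[:, 1]) < half
        )


def sample_neurons(
    w: float, mu: float | None, rng: np.random.Generator, n: int | None = None
) -> NeuronField:
    """Sample a Poisson(4 w^2 mu) number of i.i.d. uniform somata on the square.

    Passing ``n`` fixes the node count instead of drawing it (the intensity
    is then recorded as None).
    """
    if not (np.isfinite(w) and w > 0):
        raise ValueError(f"w must be > 0, got {w}")
    if n is None:
        if mu is None or not (np.isfinite(mu) and mu > 0):
            raise ValueError(f"mu must be > 0, got {mu}")
        n = int(rng.poisson(4.0 * w * w * mu))
    elif n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    positions = rng.uniform(-w, w, size=(n, 2))
    return NeuronField(half_width=w, intensity=mu, positions=positions)


@dataclass
class ConnectivityGraph:
    """Directed graph on somata with an exact formation time on every edge."""

    field: NeuronField
    growth: GrowthParams
    r: float
    src: np.ndarray  # (m,) int
    dst: np.ndarray  # (m,) int
    time: np.ndarray  # (m,) formation times in [0, t_max]
    arbors: list[Arbor] | None = None

    @property
    def t_max(self) -> float:
        return self.growth.t_max

    @property
    def n(self) -> int:
        return self.field.n

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"source_id": self.src, "target_id": self.dst, "formation_time": self.time}
        )


def _contact_matrix(
    positions: np.ndarray, theta: np.ndarray, r: float, t_max: float
) -> np.ndarray:
    """Pairwise first-contact times for single-ray (no-branching) arbors.

    Entry (v, u): time at which the ray from v in direction theta[v] first
    touches the disc of radius r around u, +inf for a miss; diagonal is inf.
    """
    rel = positions[None, :, :] - positions[:, None, :]
    d = np.hypot(rel[..., 0], rel[..., 1])
    ex = np.cos(theta)[:, None]
    ey = np.sin(theta)[:, None]
    along = ex * rel[..., 0] + ey * rel[..., 1]
    cross = ex * rel[..., 1] - ey * rel[..., 0]

    times = np.full(d.shape, np.inf)
    times[d <= r] = 0.0
    disc = r * r - cross * cross
    hit = (d > r) & (along > 0.0) & (disc >= 0.0)
    s = along[hit] - np.sqrt(disc[hit])
    s[s > t_max] = np.inf
    times[hit] = s
    np.fill_diagonal(times, np.inf)
    return times


def build_graph(
    field: NeuronField,
    growth: GrowthParams,
    r: float,
    rng: np.random.Generator,
    keep_arbors: bool = False,
    method: str = "auto",
) -> ConnectivityGraph:
    """Grow one arbor per soma and record every potential-synapse time.

    Arbors of distinct somata are independent; edges out of one soma share
    its arbor, preserving the within-source dependence.  The edge list is
    sorted by (source, target) for deterministic output.  ``method`` is
    "auto" (vectorised pairwise geometry when branching is off), "generic"
    (always per-arbor; used for cross-validation), or "fast".
    """
    if not (np.isfinite(r) and r > 0):
        raise ValueError(f"r must be > 0, got {r}")
    if method not in ("auto", "generic", "fast"):
        raise ValueError(f"unknown method {method!r}")
    n = field.n
    if n == 0:
        empty = np.empty(0)
        return ConnectivityGraph(
            field, growth, r, empty.astype(int), empty.astype(int), empty
        )

    streams = rng.spawn(n)
    use_fast = growth.branch_rate == 0.0 and method in ("auto", "fast")
    if method == "fast" and growth.branch_rate != 0.0:
        raise ValueError("fast method requires branch_rate == 0")

    arbors: list[Arbor] | None = [] if (keep_arbors and not use_fast) else None

    if use_fast:
        # with no branching each arbor is one ray; only its direction matters,
        # and it is the first (and only) draw grow_arbor would make
        theta = np.array([s.uniform(0.0, _TWO_PI) for s in streams])
        times = _contact_matrix(field.positions, theta, r, growth.t_max)
        src, dst = np.nonzero(np.isfinite(times))
        tvals = times[src, dst]
    else:
        src_l, dst_l, t_l = [], [], []
        for v in range(n):
            arbor = grow_arbor(field.positions[v], growth, streams[v])
            if arbors is not None:
                arbors.append(arbor)
            ct = first_contact_times(arbor, field.positions, r)
            ct[v] = np.inf
            hits = np.nonzero(np.isfinite(ct))[0]
            src_l.append(np.full(hits.size, v))
            dst_l.append(hits)
            t_l.append(ct[hits])
        src = np.concatenate(src_l) if src_l else np.empty(0, dtype=int)
        dst = np.concatenate(dst_l) if dst_l else np.empty(0, dtype=int)
        tvals = np.concatenate(t_l) if t_l else np.empty(0)

    order = np.lexsort((dst, src))
    return ConnectivityGraph(
        field,
        growth,
        r,
        src[order].astype(np.int64),
        dst[order].astype(np.int64),
        tvals[order],
        arbors=arbors,
    )


@dataclass
class Snapshot:
    """The static directed graph G(t): edges formed by time ``t``."""

    t: float
    half_width: float
    positions: np.ndarray  # (n, 2)
    src: np.ndarray
    dst: np.ndarray

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def m(self) -> int:
        return self.src.size

    @cached_property
    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n), dtype=np.int8)
        a[self.src, self.dst] = 1
        return a

    @property
    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.src, minlength=self.n)

    @property
    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.dst, minlength=self.n)

    def interior_mask(self) -> np.ndarray:
        half = self.half_width / 2.0
        return (np.abs(self.positions[:, 0]) < half) & (
            np.abs(self.positions[:, 1]) < half
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for i, (x, y) in enumerate(self.positions):
            g.add_node(int(i), x=float(x), y=float(y))
        g.add_edges_from(zip(self.src.tolist(), self.dst.tolist()))
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def snapshot(g: ConnectivityGraph, t: float) -> Snapshot:
    """Exact snapshot at time ``t``: keeps edges with formation_time <= t.

    Idempotent and monotone in ``t``.  A target already inside the source's
    soma disc is recorded with formation time 0 and counts as an edge for
    every t > 0; the t = 0 snapshot is always edgeless.
    """
    if not (0.0 <= t <= g.t_max):
        raise ValueError(f"t={t} outside [0, t_max={g.t_max}]")
    if t > 0:
        mask = g.time <= t
    else:
        mask = np.zeros(g.time.shape, dtype=bool)
    return Snapshot(
        t=t,
        half_width=g.field.half_width,
        positions=g.field.positions,
        src=g.src[mask],
        dst=g.dst[mask],
    )


def estimate_connection_probability(
    growth: GrowthParams,
    r: float,
    d: float,
    t,
    n_rep: int,
    rng: np.random.Generator,
):
    """Monte-Carlo estimate of the connection probability p(t, d).

    Grows ``n_rep`` independent arbors rooted at the origin and reports the
    fraction whose first contact with a disc of radius ``r`` at distance
    ``d`` occurs by each requested time, with the binomial standard error.
    ``t`` may be a scalar or an array of probe times (all sharing the same
    arbors, so estimates at different times are positively coupled exactly
    as the underlying graph process is).  ``d <= r`` returns probability 1:
    the target starts inside the soma disc.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if not (np.isfinite(r) and r > 0):
        raise ValueError(f"r must be > 0, got {r}")
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_probe = np.atleast_1d(t_arr)
    if np.any(t_probe < 0) or np.any(t_probe > growth.t_max):
        raise ValueError("probe times must lie in [0, t_max]")

    if d <= r:
        p = np.ones(t_probe.shape)
        se = np.zeros(t_probe.shape)
    else:
        target = np.array([[d, 0.0]])
        if growth.branch_rate == 0.0:
            theta = rng.uniform(0.0, _TWO_PI, size=n_rep)
            along = d * np.cos(theta)
            cross = d * np.sin(theta)
            disc = r * r - cross * cross
            contact = np.full(n_rep, np.inf)
            ok = (along > 0.0) & (disc >= 0.0)
            s = along[ok] - np.sqrt(disc[ok])
            s[s > growth.t_max] = np.inf
            contact[ok] = s
        else:
            contact = np.empty(n_rep)
            origin = np.zeros(2)
            for i in range(n_rep):
                arbor = grow_arbor(origin, growth, rng)
                contact[i] = first_contact_times(arbor, target, r)[0]
        hits = contact[None, :] <= t_probe[:, None]
        p = hits.mean(axis=1)
        se = np.sqrt(p * (1.0 - p) / n_rep)

    if scalar:
        return float(p[0]), float(se[0])
    return p, se


def write_nodes_csv(field: NeuronField, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "node_id": np.arange(field.n),
            "x": field.positions[:, 0],
            "y": field.positions[:, 1],
        }
    ).to_csv(path, index=False)


def write_edges_csv(g: ConnectivityGraph, path) -> None:
    g.to_frame().to_csv(path, index=False)
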