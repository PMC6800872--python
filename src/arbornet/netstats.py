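"""Directed network statistics of G(t) snapshots and of the G(n,m) null model.

The null model matched to a snapshot is the classical directed G(n, m):
``m`` distinct non-loop directed edges chosen uniformly without replacement
among the ``n (n-1)`` ordered pairs, with ``n`` and ``m`` equal to the
snapshot's node and edge counts.

Conventions follow the directed-graph definitions used throughout:

* the average shortest path treats every edge as one hop and counts an
  unreachable ordered pair as distance 0, which deflates averages on sparse
  graphs (``reachable_only=True`` switches to averaging over reachable
  pairs for sensitivity analysis);
* the clustering coefficient is the Fagiolo-style directed one; a node
  whose triangle denominator is zero or negative contributes 0 and stays in
  the averaging count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "DegreeSample",
    "as_adjacency",
    "connection_frequency",
    "avg_shortest_path",
    "directed_triangles",
    "clustering_coefficient",
    "sample_gnm",
    "max_degree",
]


@dataclass
class DegreeSample:
    """Aligned in/out degree sequences of one directed graph."""

    in_degrees: np.ndarray
    out_degrees: np.ndarray

    def __post_init__(self) -> None:
        self.in_degrees = np.asarray(self.in_degrees, dtype=np.int64)
        self.out_degrees = np.asarray(self.out_degrees, dtype=np.int64)
        if self.in_degrees.shape != self.out_degrees.shape:
            raise ValueError("in/out degree sequences must be aligned")

    @classmethod
    def from_graph(cls, g) -> "DegreeSample":
        a = as_adjacency(g)
        return cls(in_degrees=a.sum(axis=0), out_degrees=a.sum(axis=1))


def as_adjacency(g) -> np.ndarray:
    """Coerce a Snapshot, 0/1 matrix, or networkx DiGraph to a dense adjacency."""
    if hasattr(g, "adjacency") and not callable(getattr(g, "adjacency")):
        a = np.asarray(g.adjacency)
    elif isinstance(g, np.ndarray):
        a = g
    else:
        try:
            import networkx as nx

            if isinstance(g, nx.DiGraph):
                a = nx.to_numpy_array(g, dtype=int)
            else:
                raise TypeError
        except (ImportError, TypeError):
            raise TypeError(f"cannot interpret {type(g)!r} as a directed graph")
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be 0/1")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal (no self-loops)")
    return a.astype(np.int64)


def connection_frequency(g) -> float:
    """Fraction of realised ordered pairs: #edges / (n (n-1))."""
    a = as_adjacency(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("connection frequency needs at least 2 nodes")
    return float(a.sum() / (n * (n - 1)))


def avg_shortest_path(g, reachable_only: bool = False) -> float:
    """Directed average shortest path length in hops.

    L(G) = (1/n) sum_v [ sum_{u != v} d(v -> u) ] / (n - 1), with an
    unreachable ordered pair contributing 0.  With ``reachable_only`` the
    denominator is the number of reachable ordered pairs instead (0 if the
    graph has none).
    """
    a = as_adjacency(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("average shortest path needs at least 2 nodes")
    dist = shortest_path(csr_matrix(a), method="D", directed=True, unweighted=True)
    np.fill_diagonal(dist, np.inf)
    finite = np.isfinite(dist)
    total = dist[finite].sum()
    if reachable_only:
        k = finite.sum()
        return float(total / k) if k else 0.0
    return float(total / (n * (n - 1)))


def directed_triangles(adjacency, v: int) -> float:
    """Number of directed triangles attached to node ``v``.

    t_v = (1/2) sum_{w,u} (a_vw + a_wv)(a_vu + a_uv)(a_wu + a_uw), i.e. half
    the v-th diagonal entry of (A + A^T)^3.  Can be half-integer on
    asymmetric patterns; returned unrounded.
    """
    a = as_adjacency(adjacency)
    s = (a + a.T).astype(float)
    return float(s[v] @ s @ s[:, v] / 2.0)


def clustering_coefficient(g) -> float:
    """Fagiolo-style directed clustering coefficient, averaged over all nodes.

    Per node: t_v / (k_v (k_v - 1) - 2 sum_w a_vw a_wv) with k_v the total
    (in + out) degree; nodes with a non-positive denominator contribute 0
    and remain in the averaging count.  An empty graph has coefficient 0.
    """
    a = as_adjacency(g).astype(float)
    n = a.shape[0]
    if n == 0:
        return 0.0
    s = a + a.T
    tri = np.einsum("ij,jk,ki->i", s, s, s) / 2.0
    k_tot = a.sum(axis=0) + a.sum(axis=1)
    recip = np.einsum("ij,ji->i", a, a)
    denom = k_tot * (k_tot - 1.0) - 2.0 * recip
    contrib = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return float(contrib.mean())


def sample_gnm(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Directed G(n, m): m distinct non-loop edges uniform without replacement."""
    if n < 0 or not (0 <= m <= n * (n - 1)):
        raise ValueError(f"m={m} out of range for n={n}")
    a = np.zeros((n, n), dtype=np.int8)
    if m:
        idx = rng.choice(n * (n - 1), size=m, replace=False)
        src = idx // (n - 1)
        off = idx % (n - 1)
        dst = off + (off >= src)
        a[src, dst] = 1
    return a


def max_degree(s: DegreeSample, which: str) -> int:
    """Maximum of the chosen degree sequence ('in' or 'out')."""
    if which not in ("in", "out"):
        raise ValueError("which must be 'in' or 'out'")
    seq = s.in_degrees if which == "in" else s.out_degrees
    if seq.size == 0:
        raise ValueError("empty degree sample")
    return int(seq.max())
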