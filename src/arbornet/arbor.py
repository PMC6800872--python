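"""Branching-random-walk axonal arbors and exact geometric queries on them.

A neuron's axonal arbor is modelled as a planar branching random walk.  A ray
starts at the soma in a uniformly random direction and elongates at unit
speed.  Each living ray carries an independent exponential lifetime with rate
``branch_rate``; when the lifetime expires the ray stops and two new rays
start at its tip, each deviating from the parent direction by an independent
Uniform[-alpha, alpha] angle.  The tree at time ``t`` is the union of all
(possibly truncated) segments born up to ``t``.

The queries answered here are exact, not discretised: total branch length,
point-to-tree distance, the first time the tree touches a disc of radius
``r`` around a target (a potential synapse event), and branch length clipped
to an axis-aligned rectangle (used for boundary-effect experiments).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthParams",
    "Arbor",
    "grow_arbor",
    "arbor_length",
    "distance_to_arbor",
    "first_contact_time",
    "first_contact_times",
    "clipped_arbor_length",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the branching random walk.

    Attributes
    ----------
    branch_rate : float
        Branching intensity (rate of the exponential ray lifetime), >= 0.
        Zero disables branching: the arbor is a single growing ray.
    max_deviation : float
        Maximal angular deviation of a child ray from its parent, in radians,
        in [0, pi].  ``pi`` gives full angular randomisation (radially
        symmetric growth).
    t_max : float
        Growth horizon, > 0.  Elongation speed is fixed at 1, so times and
        lengths share one unit.
    """

    branch_rate: float
    max_deviation: float
    t_max: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.branch_rate) and self.branch_rate >= 0.0):
            raise ValueError(f"branch_rate must be finite and >= 0, got {self.branch_rate}")
        if not (np.isfinite(self.max_deviation) and 0.0 <= self.max_deviation <= math.pi):
            raise ValueError(
                f"max_deviation must lie in [0, pi], got {self.max_deviation}"
            )
        if not (np.isfinite(self.t_max) and self.t_max > 0.0):
            raise ValueError(f"t_max must be finite and > 0, got {self.t_max}")


@dataclass
class Arbor:
    """One realised axonal tree, stored as flat per-segment arrays.

    Segment 0 is the root ray.  A non-root segment starts at its parent's tip
    (the point the parent reached at its split time) and is born at that split
    time.  ``end_time`` is the segment's own split time, or ``params.t_max``
    if it never split within the horizon.
    """

    start: np.ndarray  # (n, 2) segment start points
    direction: np.ndarray  # (n,) angles in [0, 2*pi)
    birth_time: np.ndarray  # (n,)
    end_time: np.ndarray  # (n,)
    parent: np.ndarray  # (n,) int, -1 for the root
    params: GrowthParams
    seed: int | None = None
    _unit: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.start = np.atleast_2d(np.asarray(self.start, dtype=float))
        self.direction = np.asarray(self.direction, dtype=float)
        self.birth_time = np.asarray(self.birth_time, dtype=float)
        self.end_time = np.asarray(self.end_time, dtype=float)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self._unit = np.column_stack((np.cos(self.direction), np.sin(self.direction)))

    @property
    def root(self) -> np.ndarray:
        return self.start[0]

    @property
    def n_segments(self) -> int:
        return self.start.shape[0]

    @property
    def n_splits(self) -> int:
        return (self.n_segments - 1) // 2

    def lengths_at(self, t: float) -> np.ndarray:
        """Per-segment lengths at time ``t`` (zero for segments not yet born)."""
        return np.clip(np.minimum(t, self.end_time) - self.birth_time, 0.0, None)

    def tips_at(self, t: float) -> np.ndarray:
        """Per-segment tip coordinates at time ``t``."""
        return self.start + self.lengths_at(t)[:, None] * self._unit

    def to_frame(self):
        """Long-table export: one row per segment."""
        import pandas as pd

        return pd.DataFrame(
            {
                "segment_id": np.arange(self.n_segments),
                "parent_id": self.parent,
                "x0": self.start[:, 0],
                "y0": self.start[:, 1],
                "direction_rad": self.direction,
                "birth_time": self.birth_time,
                "end_time": self.end_time,
            }
        )


def grow_arbor(
    root,
    params: GrowthParams,
    rng: np.random.Generator,
    max_segments: int = 1_000_000,
) -> Arbor:
    """Simulate one arbor by event-driven construction.

    Split events are processed in chronological order off a priority queue.
    With ``branch_rate == 0`` no exponential clocks are drawn and the result
    is a single ray of length ``t_max``.  The expected number of rays is
    ``e**(branch_rate * t_max)``; ``max_segments`` guards against parameter
    combinations whose trees would not fit in memory.
    """
    root = np.asarray(root, dtype=float).reshape(-1)
    if root.shape != (2,) or not np.all(np.isfinite(root)):
        raise ValueError(f"root must be a finite point in the plane, got {root!r}")
    if not isinstance(params, GrowthParams):
        params = GrowthParams(*params)

    lam = params.branch_rate
    alpha = params.max_deviation
    t_max = params.t_max

    starts = [root]
    dirs = [rng.uniform(0.0, _TWO_PI)]
    births = [0.0]
    ends = [t_max]
    parents = [-1]

    events: list[tuple[float, int]] = []
    if lam > 0.0:
        heapq.heappush(events, (rng.exponential(1.0 / lam), 0))

    while events:
        t_split, i = heapq.heappop(events)
        if t_split >= t_max:
            break  # queue is time-ordered: nothing later can split either
        ends[i] = t_split
        length = t_split - births[i]
        tip = starts[i] + length * np.array(
            (math.cos(dirs[i]), math.sin(dirs[i]))
        )
        for _ in range(2):
            child_dir = (dirs[i] + rng.uniform(-alpha, alpha)) % _TWO_PI
            j = len(starts)
            starts.append(tip)
            dirs.append(child_dir)
            births.append(t_split)
            ends.append(t_max)
            parents.append(i)
            heapq.heappush(events, (t_split + rng.exponential(1.0 / lam), j))
        if len(starts) > max_segments:
            raise RuntimeError(
                f"arbor exceeded max_segments={max_segments}; expected ray count "
                f"is ~e**(branch_rate*t_max) = e**{lam * t_max:.3g}"
            )

    return Arbor(
        start=np.array(starts),
        direction=np.array(dirs),
        birth_time=np.array(births),
        end_time=np.array(ends),
        parent=np.array(parents),
        params=params,
    )


def _check_time(a: Arbor, t: float) -> None:
    if not (0.0 <= t <= a.params.t_max):
        raise ValueError(f"t={t} outside [0, t_max={a.params.t_max}]")


def arbor_length(a: Arbor, t: float) -> float:
    """Total branch length L_v(t): the sum of all segment lengths at ``t``."""
    _check_time(a, t)
    return float(a.lengths_at(t).sum())


def distance_to_arbor(a: Arbor, u, t: float) -> float:
    """Smallest Euclidean distance from point ``u`` to the tree at time ``t``."""
    _check_time(a, t)
    u = np.asarray(u, dtype=float)
    lengths = a.lengths_at(t)
    alive = a.birth_time <= t
    rel = u[None, :] - a.start[alive]
    proj = np.clip(np.einsum("ij,ij->i", rel, a._unit[alive]), 0.0, lengths[alive])
    closest = a.start[alive] + proj[:, None] * a._unit[alive]
    return float(np.min(np.hypot(*(u[None, :] - closest).T)))


def _segment_contact(
    starts: np.ndarray,
    units: np.ndarray,
    births: np.ndarray,
    final_lengths: np.ndarray,
    points: np.ndarray,
    r: float,
) -> np.ndarray:
    """Earliest contact time of each query disc with any segment.

    For a ray from ``x0`` in unit direction ``e``, with the target centre at
    relative position ``rel`` (distance d, angular offset phi), the first arc
    length at which the ray enters the disc of radius r is

        s0 = d*cos(phi) - sqrt(r**2 - d**2 sin(phi)**2),

    valid when cos(phi) > 0 and |d sin(phi)| <= r; a segment start already
    inside the disc contributes its birth time.  Returns +inf where no
    segment ever touches the disc.  Shapes: segments (S,), points (P, 2);
    result (P,).
    """
    rel = points[None, :, :] - starts[:, None, :]  # (S, P, 2)
    d = np.hypot(rel[..., 0], rel[..., 1])
    along = rel[..., 0] * units[:, None, 0] + rel[..., 1] * units[:, None, 1]
    cross = units[:, None, 0] * rel[..., 1] - units[:, None, 1] * rel[..., 0]

    times = np.full(d.shape, np.inf)

    inside = d <= r
    times[inside] = np.broadcast_to(births[:, None], d.shape)[inside]

    disc = r * r - cross * cross
    hit = (~inside) & (along > 0.0) & (disc >= 0.0)
    s = along[hit] - np.sqrt(disc[hit])
    reached = s <= np.broadcast_to(final_lengths[:, None], d.shape)[hit]
    t_hit = np.broadcast_to(births[:, None], d.shape)[hit][reached] + s[reached]
    idx = tuple(ax[reached] for ax in np.nonzero(hit))
    np.minimum.at(times, idx, t_hit)

    return times.min(axis=0)


def first_contact_times(a: Arbor, points, r: float) -> np.ndarray:
    """Vectorised first-contact times from one arbor to many target discs.

    Returns an array aligned with ``points``; entries are the smallest time
    ``t <= t_max`` with ``distance_to_arbor(a, u, t) <= r``, or ``+inf`` if
    the tree never touches the disc within the horizon.
    """
    if not (np.isfinite(r) and r > 0.0):
        raise ValueError(f"r must be > 0, got {r}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return _segment_contact(
        a.start,
        a._unit,
        a.birth_time,
        a.end_time - a.birth_time,
        points,
        r,
    )


def first_contact_time(a: Arbor, u, r: float) -> float | None:
    """First time the tree touches the disc of radius ``r`` around ``u``.

    Computed in closed form per segment and minimised over segments; returns
    ``None`` if there is no contact by ``t_max``.  A target within ``r`` of
    the root gives 0.
    """
    t = float(first_contact_times(a, np.asarray(u, dtype=float)[None, :], r)[0])
    return None if math.isinf(t) else t


def clipped_arbor_length(a: Arbor, t: float, region) -> float:
    """Branch length at time ``t`` lying inside an axis-aligned rectangle.

    ``region`` is ``(xmin, xmax, ymin, ymax)``; infinities give half-planes
    or quadrants.  Segments are clipped exactly at boundary crossings
    (Liang-Barsky interval intersection), so clipped lengths over a partition
    of the plane sum to ``arbor_length(a, t)`` exactly.
    """
    _check_time(a, t)
    xmin, xmax, ymin, ymax = (float(v) for v in region)
    if xmin > xmax or ymin > ymax:
        raise ValueError(f"malformed region {region!r}")

    lengths = a.lengths_at(t)
    lo = np.zeros(a.n_segments)
    hi = lengths.copy()

    for axis, (bmin, bmax) in enumerate(((xmin, xmax), (ymin, ymax))):
        p = a.start[:, axis]
        dv = a._unit[:, axis]
        parallel = np.abs(dv) < 1e-15
        outside = parallel & ((p < bmin) | (p > bmax))
        hi[outside] = -np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (bmin - p) / dv
            t2 = (bmax - p) / dv
        t_lo = np.where(parallel, -np.inf, np.minimum(t1, t2))
        t_hi = np.where(parallel, np.inf, np.maximum(t1, t2))
        lo = np.maximum(lo, t_lo)
        hi = np.minimum(hi, t_hi)

    return float(np.clip(hi - lo, 0.0, None).sum())
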