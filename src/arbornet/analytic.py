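"""Closed-form and numerical evaluation of connection-probability and degree laws.

For a single non-branching ray grown at unit speed from a soma, the
probability that it has touched the disc of radius ``r`` around a target at
distance ``d > r`` by time ``t`` has the exact piecewise form ``p0(t, d)``
(zero before the ray can reach, an arccos transition while the reachable
angular window opens, then the saturated value ``arcsin(r/d)/pi``).

With branching at rate ``lam`` and full angular randomisation (alpha = pi),
the no-connection probability ``q(t, d) = 1 - p(t, d)`` satisfies a
Volterra-type integral equation obtained by conditioning on the first split:
either the root ray splits at time ``s`` before reaching the disc, leaving
two independent subtrees that must both avoid the target from the split
point, or it never splits by ``t`` and must itself avoid the disc.
``solve_q_pi`` marches this equation forward in time on a (t, d) grid.

Degree laws used throughout: the out-degree of an interior neuron is Poisson
with mean ``intensity * area(r-neighbourhood of the tree)``; with no
branching that area is exactly ``2*r*t + pi*r**2``, and the in-degree mean is
the radial integral of ``p0`` against the Poisson field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate, stats

__all__ = [
    "p0",
    "expected_length",
    "expected_out_degree",
    "out_degree_pmf_lambda0",
    "in_degree_rate_lambda0",
    "InDegreeRate",
    "ProbabilityGrid",
    "solve_q_pi",
    "hub_regime",
    "HubDiagnostic",
]


def p0(t, d, r: float):
    """Connection probability for a single non-branching ray.

    Piecewise in ``t`` for fixed target distance ``d > r``:

    * 0 while ``t < d - r`` (the ray cannot have reached the disc);
    * ``arccos((d**2 + t**2 - r**2) / (2*t*d)) / pi`` for
      ``d - r <= t <= sqrt(d**2 - r**2)``;
    * the saturated value ``arcsin(r/d) / pi`` afterwards.

    Continuous at both breakpoints and non-decreasing in ``t``.  Broadcasts
    over array ``t`` and ``d``.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (np.isfinite(r) and r >= 0.0):
        raise ValueError(f"r must be finite and >= 0, got {r}")
    if np.any(d <= r):
        raise ValueError("p0 requires d > r (targets outside the soma disc)")
    if np.any(t < 0.0):
        raise ValueError("p0 requires t >= 0")

    t_b, d_b = np.broadcast_arrays(t, d)
    out = np.zeros(t_b.shape)

    saturated = t_b > np.sqrt(d_b * d_b - r * r)
    out[saturated] = np.arcsin(r / d_b[saturated]) / math.pi

    # strict inequality: at t = d - r the transition branch is arccos(1) = 0,
    # but evaluating it there amplifies rounding to ~sqrt(eps); assigning the
    # breakpoint to the zero branch gives the identical value exactly
    mid = (~saturated) & (t_b > d_b - r) & (t_b > 0.0)
    arg = (d_b[mid] ** 2 + t_b[mid] ** 2 - r * r) / (2.0 * t_b[mid] * d_b[mid])
    out[mid] = np.arccos(np.clip(arg, -1.0, 1.0)) / math.pi

    if out.ndim == 0:
        return float(out)
    return out


def expected_length(lam: float, t):
    """Expected total branch length E L_v(t) = (e**(lam*t) - 1) / lam.

    Continuous at ``lam = 0`` where the value is ``t`` (a single ray at unit
    speed).  Accepts array ``t``.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if lam == 0.0:
        out = t.copy()
    else:
        out = np.expm1(lam * t) / lam
    return float(out) if out.ndim == 0 else out


def expected_out_degree(lam: float, r: float, mu: float, t):
    """Leading-order expected out-degree of an interior neuron.

    ``2 * r * mu * E L_v(t)``: the r-neighbourhood of a tree of total length
    L has area ``~2 r L`` for small r, and the soma field has intensity mu.
    """
    if r < 0 or mu < 0:
        raise ValueError("r and mu must be >= 0")
    length = expected_length(lam, t)
    return 2.0 * r * mu * length


def out_degree_pmf_lambda0(k, r: float, t: float, mu: float):
    """Exact out-degree pmf with no branching: Poisson((2*r*t + pi*r**2)*mu).

    The r-neighbourhood of a single segment of length t is a stadium of area
    ``2*r*t + pi*r**2`` exactly, so for an interior neuron the out-degree is
    Poisson with that area times the intensity.
    """
    k = np.asarray(k)
    if np.any(k != np.floor(k)) or np.any(k < 0):
        raise ValueError("k must be a non-negative integer")
    mean = (2.0 * r * t + math.pi * r * r) * mu
    out = stats.poisson.pmf(k, mean)
    return float(out) if np.ndim(out) == 0 else out


class InDegreeRate(NamedTuple):
    """Poisson mean of the no-branching in-degree, and its leading approximation."""

    value: float
    leading: float  # 2 * mu * r * t


def in_degree_rate_lambda0(r: float, t: float, mu: float) -> InDegreeRate:
    """Poisson mean of the in-degree of a central neuron with no branching.

    Integrates the saturated connection probability radially against the
    Poisson field: ``int_r^sqrt(t^2+r^2) 2*x*mu*arcsin(r/x) dx``.  Also
    returns the leading small-r approximation ``2*mu*r*t``; the two differ
    by O(r**(3/2) * mu).
    """
    if not (0.0 < r < t):
        raise ValueError(f"requires 0 < r < t, got r={r}, t={t}")
    upper = math.sqrt(t * t + r * r)
    value, _ = integrate.quad(
        lambda x: 2.0 * x * mu * math.asin(min(r / x, 1.0)), r, upper, limit=200
    )
    return InDegreeRate(value=value, leading=2.0 * mu * r * t)


@dataclass
class ProbabilityGrid:
    """Tabulated no-connection probabilities q(t, d) on a rectangular grid."""

    t_grid: np.ndarray
    d_grid: np.ndarray
    values: np.ndarray  # (nt, nd), q in [0, 1]
    branch_rate: float
    r: float

    def q(self, t, d):
        """Bilinear interpolation of q at (t, d); clamps to the grid edges."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.t_grid, self.d_grid),
            self.values,
            bounds_error=False,
            fill_value=None,
        )
        t = np.asarray(t, dtype=float)
        d = np.asarray(d, dtype=float)
        tb, db = np.broadcast_arrays(
            np.clip(t, self.t_grid[0], self.t_grid[-1]),
            np.clip(d, self.d_grid[0], self.d_grid[-1]),
        )
        out = interp(np.stack([tb.ravel(), db.ravel()], axis=-1)).reshape(tb.shape)
        return float(out) if out.ndim == 0 else out

    def p(self, t, d):
        """Connection probability 1 - q."""
        return 1.0 - self.q(t, d)

    def to_frame(self):
        """Long-format table with columns (t, d, q, p)."""
        import pandas as pd

        tt, dd = np.meshgrid(self.t_grid, self.d_grid, indexing="ij")
        return pd.DataFrame(
            {
                "t": tt.ravel(),
                "d": dd.ravel(),
                "q": self.values.ravel(),
                "p": 1.0 - self.values.ravel(),
            }
        )


def _q0(t, d, r):
    """No-connection probability for a single ray (1 - p0), broadcasting."""
    return 1.0 - p0(t, d, r)


def solve_q_pi(
    lam: float,
    r: float,
    t_grid,
    d_grid,
    n_phi: int = 48,
    fp_tol: float = 1e-6,
    max_sweeps: int = 40,
) -> ProbabilityGrid:
    """Solve the alpha = pi no-connection integral equation by time marching.

    The equation conditions on the first split of the root ray at time
    ``s`` with angular offset ``phi`` from the target direction (uniform on
    the circle).  If the ray points at the disc (|phi| < phi0 = arcsin(r/d))
    it would touch at arc length ``s0(phi) = d cos(phi) - sqrt(r^2 - d^2
    sin^2(phi))``, so only splits with ``s < s0`` leave a no-connection
    branch; otherwise any split time up to ``t`` does.  Both children are
    independent full trees at distance ``d~(d, s, phi) = sqrt(d^2 + s^2 -
    2 d s cos(phi))`` from the target, contributing ``q(t-s, d~)**2``.  The
    no-split event contributes ``e**(-lam t) q0(t, d)``.

    Quadrature is trapezoidal in both ``s`` (aligned with the uniform time
    grid, with the ``s0`` cutoff handled by a partial last cell) and ``phi``
    (``n_phi`` nodes per symmetric half-sector); ``d~`` is looked up by
    linear interpolation in ``d``; any off-grid state with ``tau <= delta -
    r`` is exactly 1 (the tree cannot reach).  The ``s = 0`` endpoint couples
    the current time layer to itself; since ``d~(d, 0, phi) = d`` that
    coupling is a scalar quadratic per distance node, resolved by a few
    fixed-point sweeps.

    At ``lam = 0`` the branching terms carry a factor ``lam e**(-lam s) = 0``
    identically, so the solution is the closed form ``q0`` and is returned
    exactly without quadrature.
    """
    t = np.asarray(t_grid, dtype=float)
    d = np.asarray(d_grid, dtype=float)
    if lam < 0 or r <= 0:
        raise ValueError("requires lam >= 0 and r > 0")
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be increasing with at least 2 points")
    if abs(t[0]) > 1e-12:
        raise ValueError("t_grid must start at 0")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-8):
        raise ValueError("t_grid must be uniform")
    if d.ndim != 1 or d.size < 2 or np.any(np.diff(d) <= 0):
        raise ValueError("d_grid must be increasing with at least 2 points")
    if d[0] <= r:
        raise ValueError(f"d_grid must start above r={r}")

    nt, nd = t.size, d.size
    q0_grid = _q0(t[:, None], d[None, :], r)

    if lam == 0.0:
        return ProbabilityGrid(t, d, q0_grid, lam, r)

    dt = float(steps[0])
    xs = np.linspace(0.0, 1.0, n_phi)

    phi0 = np.arcsin(r / d)  # (nd,)
    # sector 1: |phi| < phi0, ray aimed at the disc; nodes scaled per distance
    phi1 = phi0[:, None] * xs[None, :]  # (nd, n_phi)
    s0 = d[:, None] * np.cos(phi1) - np.sqrt(
        np.maximum(r * r - (d[:, None] * np.sin(phi1)) ** 2, 0.0)
    )
    # sector 2: phi in (phi0, pi), ray misses the disc entirely
    phi2 = phi0[:, None] + (math.pi - phi0)[:, None] * xs[None, :]

    def _trap_weights(width):  # width: (nd,) sector width; doubled for symmetry
        w = np.full((nd, n_phi), 1.0)
        w[:, 0] = w[:, -1] = 0.5
        return 2.0 * w * (width / (n_phi - 1))[:, None]

    w_phi1 = _trap_weights(phi0)
    w_phi2 = _trap_weights(math.pi - phi0)

    cos1 = np.cos(phi1)
    cos2 = np.cos(phi2)

    Q = np.empty((nt, nd))
    Q[0] = 1.0

    d2 = d * d

    for i in range(1, nt):
        ti = t[i]
        ls = np.arange(i + 1)
        s = ls * dt  # (ns,)
        tau = ti - s  # time argument of q at each s node (grid-aligned)
        dens = lam * np.exp(-lam * s) / (2.0 * math.pi)

        # s-quadrature weights, sector 2: full trapezoid on [0, ti]
        w2 = np.full(i + 1, dt)
        w2[0] = w2[-1] = dt / 2.0

        # sector 1: trapezoid up to the cutoff U = min(s0, ti), with a
        # left-rectangle partial cell [L*dt, U]
        U = np.minimum(s0, ti)  # (nd, n_phi)
        L = np.minimum(np.floor(U / dt + 1e-12).astype(int), i)
        lg = ls[None, None, :]
        w1 = dt * (lg <= L[:, :, None]).astype(float)
        w1[:, :, 0] -= dt / 2.0
        at_L = lg == L[:, :, None]
        w1 -= (dt / 2.0) * at_L
        w1 += (U - L * dt)[:, :, None] * at_L

        # q(tau_l, d~) for l >= 1 (layers already final); l = 0 handled below
        def _branch_sum(cosphi, w_s):
            # d~ over (nd, n_phi, ns>=1)
            dtil = np.sqrt(
                np.maximum(
                    d2[:, None, None]
                    + (s[1:] ** 2)[None, None, :]
                    - 2.0 * d[:, None, None] * s[None, None, 1:] * cosphi[:, :, None],
                    0.0,
                )
            )
            j0 = np.clip(np.searchsorted(d, dtil) - 1, 0, nd - 2)
            wd = np.clip((dtil - d[j0]) / (d[j0 + 1] - d[j0]), 0.0, 1.0)
            rows = Q[i - ls[1:]]  # (ns-1, nd); rows[l-1] = q(tau_l, .)
            lidx = np.arange(i)[None, None, :]
            qv = rows[lidx, j0] * (1.0 - wd) + rows[lidx, j0 + 1] * wd
            # exact shortcut: the tree cannot reach the disc at all
            qv[tau[None, None, 1:] <= dtil - r] = 1.0
            return (qv * qv * dens[None, None, 1:] * w_s[:, :, 1:]).sum(axis=2)

        A1 = _branch_sum(cos1, w1)
        A2 = _branch_sum(cos2, np.broadcast_to(w2[None, None, :], w1.shape))
        K = (A1 * w_phi1).sum(axis=1) + (A2 * w_phi2).sum(axis=1)
        K += math.exp(-lam * ti) * q0_grid[i]

        # l = 0 coupling: d~(d, 0, phi) = d exactly, so the current layer
        # enters as c_j * q_j**2 with a scalar weight per distance node
        c = dens[0] * ((w1[:, :, 0] * w_phi1).sum(axis=1) + (w2[0] * w_phi2).sum(axis=1))

        q_cur = Q[i - 1].copy()
        for _ in range(max_sweeps):
            q_new = np.clip(K + c * q_cur * q_cur, 0.0, 1.0)
            q_new[ti <= d - r] = 1.0
            if np.max(np.abs(q_new - q_cur)) < fp_tol:
                q_cur = q_new
                break
            q_cur = q_new
        Q[i] = q_cur

    return ProbabilityGrid(t, d, Q, lam, r)


@dataclass(frozen=True)
class HubDiagnostic:
    """Coarse parameter-regime label with the dimensionless products behind it."""

    label: str  # "sub-critical" | "near-constant" | "hub-regime"
    products: dict


def hub_regime(mu: float, r: float, t: float, lam: float = 0.0) -> HubDiagnostic:
    """Classify the parameter regime governing the maximal out-degree.

    Purely diagnostic.  The asymptotic order relations are operationalised
    with explicit factors: "x << y" as ``x <= y/10`` and "order 1" as a ratio
    in [1/10, 10].

    With no branching the drivers are ``mu**2 * r * t`` (max degree vanishes
    below 1/10, hubs emerge above 10 provided the axon stays thin,
    ``mu * r * t <= 1/10``).  With branching the driver is
    ``mu * r * e**(lam*t)``: of order one means a near-constant max degree;
    far below with ``mu**2 * r * e**(lam*t) <= 1/10`` is sub-critical;
    anything larger is the hub regime.
    """
    if mu <= 0 or r <= 0 or t <= 0 or lam < 0:
        raise ValueError("requires mu, r, t > 0 and lam >= 0")
    if lam == 0.0:
        z1 = mu * mu * r * t
        z2 = mu * r * t
        products = {"mu2_r_t": z1, "mu_r_t": z2}
        if z1 <= 0.1:
            label = "sub-critical"
        elif z1 >= 10.0 and z2 <= 0.1:
            label = "hub-regime"
        else:
            label = "near-constant"
    else:
        y = mu * r * math.exp(lam * t)
        products = {"mu_r_exp_lam_t": y, "mu2_r_exp_lam_t": mu * y}
        if 0.1 <= y <= 10.0:
            label = "near-constant"
        elif mu * y <= 0.1:
            label = "sub-critical"
        else:
            label = "hub-regime"
    return HubDiagnostic(label=label, products=products)
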