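"""Unit and property tests for the branching-random-walk arbor geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import ks_2samp

from arbornet import (
    GrowthParams,
    arbor_length,
    clipped_arbor_length,
    distance_to_arbor,
    first_contact_time,
    grow_arbor,
)
from conftest import make_arbor

E = math.e


class TestGrowth:
    def test_no_branching_gives_single_full_length_ray(self, rng):
        a = grow_arbor((0.5, -0.2), GrowthParams(0.0, math.pi, 3.0), rng)
        assert a.n_segments == 1
        assert arbor_length(a, 3.0) == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "lam,alpha,t_max",
        [(-1.0, math.pi, 1.0), (1.0, 4.0, 1.0), (1.0, math.pi, 0.0), (math.nan, 1.0, 1.0)],
    )
    def test_invalid_growth_params_rejected(self, lam, alpha, t_max):
        with pytest.raises(ValueError):
            GrowthParams(lam, alpha, t_max)

    def test_non_finite_root_rejected(self, rng):
        with pytest.raises(ValueError):
            grow_arbor((math.inf, 0.0), GrowthParams(0.0, math.pi, 1.0), rng)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 999),
        lam=st.floats(0.5, 3.0),
        alpha=st.floats(0.05, math.pi),
        t_max=st.floats(0.2, 1.2),
    )
    def test_binary_split_bookkeeping(self, seed, lam, alpha, t_max):
        """Every split replaces one ray by two; children start at the parent tip
        with directions within the deviation cone."""
        a = make_arbor(seed, lam, alpha, t_max)
        assert a.n_segments == 2 * a.n_splits + 1
        assert np.all(a.end_time >= a.birth_time)
        assert np.all(a.end_time <= t_max)
        for j in range(1, a.n_segments):
            i = a.parent[j]
            tip = a.start[i] + (a.end_time[i] - a.birth_time[i]) * np.array(
                [math.cos(a.direction[i]), math.sin(a.direction[i])]
            )
            assert np.allclose(a.start[j], tip, atol=1e-12)
            assert a.birth_time[j] == a.end_time[i]
            dev = (a.direction[j] - a.direction[i] + math.pi) % (2 * math.pi) - math.pi
            assert abs(dev) <= alpha + 1e-12

    def test_mean_total_length_matches_branching_formula(self):
        """E L(t) = (e^{lam t} - 1)/lam, checked by Monte Carlo at lam=1, t=1."""
        n = 4000
        lengths = np.array(
            [arbor_length(make_arbor(s, 1.0, math.pi, 1.0), 1.0) for s in range(n)]
        )
        se = lengths.std(ddof=1) / math.sqrt(n)
        assert abs(lengths.mean() - (E - 1.0)) < 3 * se

    def test_mean_live_ray_count_is_exponential(self):
        """The number of live rays at t is a Yule process with mean e^{lam t}."""
        n = 3000
        counts = np.array(
            [
                np.sum(make_arbor(s, 1.0, math.pi, 1.0).end_time == 1.0)
                for s in range(n)
            ]
        )
        se = counts.std(ddof=1) / math.sqrt(n)
        assert abs(counts.mean() - E) < 3 * se

    def test_max_segments_guard(self, rng):
        with pytest.raises(RuntimeError, match="max_segments"):
            grow_arbor((0, 0), GrowthParams(20.0, math.pi, 1.0), rng, max_segments=50)


class TestLengthQueries:
    def test_single_ray_length_grows_linearly(self, single_ray):
        assert arbor_length(single_ray, 0.7) == pytest.approx(0.7)
        assert arbor_length(single_ray, 0.0) == 0.0

    def test_length_out_of_range_rejected(self, single_ray):
        with pytest.raises(ValueError):
            arbor_length(single_ray, 3.5)
        with pytest.raises(ValueError):
            arbor_length(single_ray, -0.1)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 500))
    def test_length_nondecreasing_and_zero_at_origin(self, seed):
        a = make_arbor(seed)
        ts = np.linspace(0.0, a.params.t_max, 40)
        lengths = [arbor_length(a, t) for t in ts]
        assert lengths[0] == 0.0
        assert np.all(np.diff(lengths) >= -1e-12)


class TestDistance:
    def test_point_to_segment_examples(self, single_ray):
        # perpendicular foot interior, nearest point at tip, nearest at root
        assert distance_to_arbor(single_ray, (1.0, 1.0), 2.0) == pytest.approx(1.0)
        assert distance_to_arbor(single_ray, (3.0, 0.0), 2.0) == pytest.approx(1.0)
        assert distance_to_arbor(single_ray, (-1.0, 0.0), 2.0) == pytest.approx(1.0)

    def test_distance_at_time_zero_is_root_distance(self, single_ray):
        assert distance_to_arbor(single_ray, (3.0, 4.0), 0.0) == pytest.approx(5.0)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 300))
    def test_distance_nonincreasing_in_time(self, seed):
        a = make_arbor(seed)
        u = np.random.default_rng(seed + 1).uniform(-1.5, 1.5, 2)
        ds = [distance_to_arbor(a, u, t) for t in np.linspace(0, a.params.t_max, 30)]
        assert np.all(np.diff(ds) <= 1e-12)

    def test_rotational_invariance_of_radially_symmetric_growth(self):
        """With alpha=pi the law of the point-to-tree distance is rotation
        invariant about the root (two-sample KS on Monte-Carlo samples)."""
        n = 1500
        d1 = np.empty(n)
        d2 = np.empty(n)
        c, s = math.cos(1.1), math.sin(1.1)
        u = np.array([0.6, 0.2])
        u_rot = np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])
        for i in range(n):
            d1[i] = distance_to_arbor(make_arbor(i, 1.0, math.pi, 0.8), u, 0.8)
            d2[i] = distance_to_arbor(make_arbor(n + i, 1.0, math.pi, 0.8), u_rot, 0.8)
        assert ks_2samp(d1, d2).pvalue > 0.01


class TestFirstContact:
    def test_head_on_contact(self, single_ray):
        assert first_contact_time(single_ray, (1.0, 0.0), 0.1) == pytest.approx(0.9)

    def test_ray_missing_the_disc(self, single_ray):
        # |d sin(phi)| > r: the ray passes wide of the disc
        assert first_contact_time(single_ray, (1.0, 0.3), 0.1) is None

    def test_oblique_contact_matches_closed_form(self):
        """Contact arc length d cos(phi) - sqrt(r^2 - d^2 sin^2 phi) at
        d=1, r=0.1, phi=0.05, cross-checked by dense sampling along the ray."""
        phi = 0.05
        params = GrowthParams(0.0, math.pi, 3.0)
        from arbornet import Arbor

        a = Arbor(
            start=np.array([[0.0, 0.0]]),
            direction=np.array([phi]),
            birth_time=np.array([0.0]),
            end_time=np.array([3.0]),
            parent=np.array([-1]),
            params=params,
        )
        t_contact = first_contact_time(a, (1.0, 0.0), 0.1)
        expected = math.cos(phi) - math.sqrt(0.1**2 - math.sin(phi) ** 2)
        assert t_contact == pytest.approx(expected, abs=1e-12)
        assert t_contact == pytest.approx(0.9121356967, abs=1e-9)
        # dense sampling: the first sampled arc length within r of the target
        ss = np.linspace(0, 3, 300001)
        pts = ss[:, None] * np.array([math.cos(phi), math.sin(phi)])
        within = np.hypot(pts[:, 0] - 1.0, pts[:, 1]) <= 0.1
        assert abs(ss[within][0] - t_contact) < 2e-5

    def test_target_inside_root_ball_contacts_at_zero(self, single_ray):
        assert first_contact_time(single_ray, (0.05, 0.0), 0.1) == 0.0

    def test_nonpositive_radius_rejected(self, single_ray):
        with pytest.raises(ValueError):
            first_contact_time(single_ray, (1.0, 0.0), 0.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 400))
    def test_first_contact_is_infimum_of_distance_crossing(self, seed):
        """first_contact_time agrees with a fine-grid + bisection oracle on
        the point-to-tree distance function, to 1e-9."""
        a = make_arbor(seed, 1.5, math.pi, 1.0)
        urng = np.random.default_rng(10_000 + seed)
        u = urng.uniform(-1.0, 1.0, 2)
        r = 0.15
        t_star = first_contact_time(a, u, r)
        f = lambda t: distance_to_arbor(a, u, t) - r
        if t_star is None:
            assert f(a.params.t_max) > 0
            return
        if t_star == 0.0:
            assert np.hypot(*(u - a.root)) <= r
            return
        grid = np.linspace(0.0, a.params.t_max, 2001)
        vals = np.array([f(t) for t in grid])
        first_inside = np.argmax(vals <= 0)
        assert first_inside > 0, "oracle grid should bracket the crossing"
        t_oracle = brentq(
            f, grid[first_inside - 1], grid[first_inside], xtol=1e-12
        )
        assert t_star == pytest.approx(t_oracle, abs=1e-9)


class TestClippedLength:
    def test_halfplane_clipping(self, single_ray):
        right = (0.0, math.inf, -math.inf, math.inf)
        left = (-math.inf, 0.0, -math.inf, math.inf)
        assert clipped_arbor_length(single_ray, 2.0, right) == pytest.approx(2.0)
        assert clipped_arbor_length(single_ray, 2.0, left) == pytest.approx(0.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 300))
    def test_quadrant_partition_conserves_length(self, seed):
        """Clipped lengths over the four quadrants sum exactly to the total."""
        a = make_arbor(seed, 2.0, math.pi, 0.8)
        inf = math.inf
        quads = [
            (0, inf, 0, inf),
            (-inf, 0, 0, inf),
            (0, inf, -inf, 0),
            (-inf, 0, -inf, 0),
        ]
        total = sum(clipped_arbor_length(a, 0.8, q) for q in quads)
        assert total == pytest.approx(arbor_length(a, 0.8), abs=1e-9)

    def test_quadrant_carries_quarter_of_expected_mass(self):
        """Radial symmetry: each quadrant holds 1/4 of the expected length."""
        n = 3000
        vals = np.array(
            [
                clipped_arbor_length(
                    make_arbor(s, 1.0, math.pi, 0.5), 0.5, (0, math.inf, 0, math.inf)
                )
                for s in range(n)
            ]
        )
        expected = (math.exp(0.5) - 1.0) / 4.0
        se = vals.std(ddof=1) / math.sqrt(n)
        assert abs(vals.mean() - expected) < 3 * se

    def test_malformed_region_rejected(self, single_ray):
        with pytest.raises(ValueError):
            clipped_arbor_length(single_ray, 1.0, (1.0, -1.0, 0.0, 1.0))
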