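"""Scan statistic, Voronoi adjacency, BYM detection and hull geometry."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull, Delaunay
from shapely.geometry import MultiPoint, Polygon, box

from deprivix.cluster_detection import (
    BymSpec,
    bernoulli_scan,
    fit_bym,
    hull_area,
    hull_overlap,
    voronoi_adjacency,
)


def _brute_force_scan_max(locs, labs, max_frac=0.5):
    from scipy.spatial.distance import cdist

    N = len(labs)
    C = int(labs.sum())
    kmax = int(np.floor(max_frac * N))
    D = cdist(locs, locs)

    def xl(a, b):
        return a * np.log(b) if a > 0 else 0.0

    best = -np.inf
    for i in range(N):
        order = np.argsort(D[i], kind="stable")
        for k in range(1, kmax + 1):
            z = order[:k]
            c = int(labs[z].sum())
            if c / k <= (C - c) / max(N - k, 1):
                continue
            llr = (xl(c, c / k) + xl(k - c, (k - c) / k)
                   + xl(C - c, (C - c) / (N - k))
                   + xl(N - k - (C - c), (N - k - (C - c)) / (N - k))
                   - (xl(C, C / N) + xl(N - C, (N - C) / N)))
            best = max(best, llr)
    return best


class TestBernoulliScan:
    def test_pure_cluster_closed_form(self):
        loc = np.array([[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]])
        lab = np.array([1, 1, 1, 0, 0, 0])
        res = bernoulli_scan(loc, lab, n_mc=99, seed=1)
        # all 3 cases in one circle of 3: LLR = 6 log 2
        assert res.llr == pytest.approx(6 * np.log(2.0))
        assert sorted(res.members.tolist()) == [0, 1, 2]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        locs = rng.uniform(0, 10, (25, 2))
        labs = (rng.uniform(size=25) < 0.4).astype(int)
        if labs.sum() in (0, 25):
            labs[0] = 1 - labs[0]
        res = bernoulli_scan(locs, labs, n_mc=9, seed=0)
        assert res.llr == pytest.approx(_brute_force_scan_max(locs, labs))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        locs = rng.uniform(0, 10, (40, 2))
        labs = (rng.uniform(size=40) < 0.5).astype(int)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = locs @ R.T + np.array([55.0, -3.0])
        a = bernoulli_scan(locs, labs, n_mc=49, seed=3)
        b = bernoulli_scan(moved, labs, n_mc=49, seed=3)
        assert a.llr == pytest.approx(b.llr)
        assert sorted(a.members.tolist()) == sorted(b.members.tolist())
        assert a.p_value == b.p_value

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_scan(np.random.default_rng(0).uniform(0, 1, (10, 2)),
                           np.ones(10, int))

    def test_p_value_resolution(self):
        # p = rank/(n_mc+1) can never be zero
        rng = np.random.default_rng(1)
        res = bernoulli_scan(rng.uniform(0, 1, (20, 2)),
                             (rng.uniform(size=20) < 0.5).astype(int),
                             n_mc=19, seed=0)
        assert 1 / 20 <= res.p_value <= 1.0


class TestVoronoiAdjacency:
    def test_triangle_all_adjacent(self):
        adj = voronoi_adjacency(np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]]))
        assert adj == [[1, 2], [0, 2], [0, 1]]

    def test_symmetric_no_self(self):
        rng = np.random.default_rng(2)
        adj = voronoi_adjacency(rng.uniform(0, 10, (30, 2)))
        for i, nbrs in enumerate(adj):
            assert i not in nbrs
            for j in nbrs:
                assert i in adj[j]

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            voronoi_adjacency(pts)

    def test_delaunay_duality(self):
        """Adjacency is a subset of the Delaunay edges; edges missing from
        the clipped diagram involve only near-boundary points."""
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10, (40, 2))
        adj = voronoi_adjacency(pts)
        vedges = {(i, j) for i, a in enumerate(adj) for j in a if j > i}
        dedges = set()
        for s in Delaunay(pts).simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    dedges.add((min(s[a], s[b]), max(s[a], s[b])))
        assert vedges <= dedges
        hull = MultiPoint(pts.tolist()).convex_hull
        from shapely.geometry import Point

        near_boundary = {i for i, p in enumerate(pts)
                         if hull.exterior.distance(Point(p)) < 1.5}
        for i, j in dedges - vedges:
            assert i in near_boundary or j in near_boundary


class TestBym:
    def test_null_calibration(self):
        fracs = []
        for s in range(3):
            rng = np.random.default_rng(s)
            pts = rng.uniform(0, 30, (200, 2))
            labs = (rng.uniform(size=200) < 0.5).astype(int)
            res = fit_bym(pts, labs, BymSpec(n_burn=1500, n_save=2000, seed=s))
            fracs.append(len(res.members) / 200)
        assert np.mean(fracs) <= 0.10

    def test_recovers_injected_disk(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 30, (600, 2))
        inside = np.hypot(pts[:, 0] - 15, pts[:, 1] - 15) <= 5
        eta = -0.2 + 2.0 * inside
        labs = (rng.uniform(size=600) < 1 / (1 + np.exp(-eta))).astype(int)
        res = fit_bym(pts, labs, BymSpec(n_burn=2500, n_save=3000, seed=9))
        mem = set(res.members.tolist())
        disk = set(np.flatnonzero(inside).tolist())
        jaccard = len(mem & disk) / len(mem | disk)
        assert jaccard > 0.5
        # exceedance probabilities live in [0, 1] and match the flags
        assert ((res.exceedance >= 0) & (res.exceedance <= 1)).all()
        assert set(np.flatnonzero(res.exceedance > 0.90)) == mem


class TestHulls:
    def test_unit_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert hull_area(pts) == pytest.approx(1.0)

    def test_degenerate(self):
        assert hull_area(np.array([[0.0, 0.0], [1.0, 1.0]])) == 0.0
        assert hull_area(np.zeros((0, 2))) == 0.0

    def test_matches_scipy_hull(self, rng):
        pts = rng.uniform(0, 10, (50, 2))
        assert hull_area(pts) == pytest.approx(ConvexHull(pts).volume)

    def test_overlap_identical_and_disjoint(self):
        a = box(0, 0, 1, 1)
        b = box(5, 5, 6, 6)
        inter, pct, flag = hull_overlap(a, a)
        assert pct == pytest.approx(100.0) and flag
        inter, pct, flag = hull_overlap(a, b)
        assert inter == 0.0 and pct == 0.0 and not flag

    def test_half_overlap_monte_carlo(self, rng):
        a = box(0, 0, 1, 1)
        b = box(0.5, 0, 1.5, 1)
        inter, pct, flag = hull_overlap(a, b)
        pts = rng.uniform(0, 1, (200_000, 2))
        mc = np.mean((pts[:, 0] >= 0.5))  # fraction of a's area inside b
        assert pct == pytest.approx(100 * mc, abs=1.0)
        assert pct == pytest.approx(50.0, abs=1e-9)

    def test_degenerate_polygon_zero_overlap(self):
        line = Polygon()  # empty polygon
        assert hull_overlap(line, box(0, 0, 1, 1)) == (0.0, 0.0, False)
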