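"""Adaptive-LoCoH geometry: neighbour selection, polytopes, grid occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog
from scipy.spatial import ConvexHull

from misi import (
    GridSpec,
    LocohParams,
    build_polytope,
    individual_hypervolume,
    neighbor_set,
    occupancy,
    union_volume,
)
from misi.locoh import GridError, Hypervolume, local_polytopes


def lp_point_in_hull(vertices, p):
    """Independent oracle: p ∈ conv(vertices) iff ∃ λ ≥ 0, Σλ = 1, Vᵀλ = p."""
    v = np.asarray(vertices, float)
    n, d = v.shape
    A_eq = np.vstack([v.T, np.ones(n)])
    b_eq = np.concatenate([np.asarray(p, float), [1.0]])
    res = linprog(np.zeros(n), A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * n, method="highs")
    return res.status == 0


def shoelace(points):
    """2-D polygon area from the vertex ring (independent of Qhull)."""
    h = ConvexHull(points)
    ring = points[h.vertices]
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


class TestNeighborSet:
    def test_cumulative_distance_prefix(self):
        cloud = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        nbrs = neighbor_set(cloud, 0, a=3.0)
        assert nbrs.tolist() == [1, 2]  # cumsum 1, 3; adding 3 would give 6

    def test_a_below_nearest_neighbour_gives_empty(self):
        cloud = np.array([[0.0, 0], [5, 0], [9, 0]])
        assert neighbor_set(cloud, 0, a=4.0).size == 0

    def test_infinite_a_selects_all_others(self):
        rng = np.random.default_rng(0)
        cloud = rng.normal(size=(12, 3))
        nbrs = neighbor_set(cloud, 4, a=np.inf)
        assert sorted(nbrs.tolist()) == [i for i in range(12) if i != 4]

    def test_distance_ties_broken_by_index(self):
        cloud = np.array([[0.0, 0], [1, 0], [-1, 0], [0, 1]])
        nbrs = neighbor_set(cloud, 0, a=2.0)
        assert nbrs.tolist() == [1, 2]  # all at distance 1; ascending index

    @given(st.integers(0, 9), st.floats(0.1, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_prefix_property(self, focal, a):
        rng = np.random.default_rng(99)
        cloud = rng.uniform(0, 10, size=(10, 2))
        nbrs = neighbor_set(cloud, focal, a)
        d = np.linalg.norm(cloud - cloud[focal], axis=1)
        assert d[nbrs].sum() <= a
        # maximality: the next-nearest excluded point would overflow the budget
        excluded = [i for i in range(10) if i != focal and i not in nbrs]
        if excluded:
            nxt = min(d[excluded])
            assert d[nbrs].sum() + nxt > a


class TestBuildPolytope:
    def test_right_triangle_area(self):
        cloud = np.array([[0.0, 0], [1, 0], [0, 1]])
        poly = build_polytope(cloud, 0, np.array([1, 2]))
        assert poly.measure == pytest.approx(0.5)

    def test_unit_simplex_volume(self):
        cloud = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        poly = build_polytope(cloud, 0, np.array([1, 2, 3]))
        assert poly.measure == pytest.approx(1.0 / 6.0)

    def test_collinear_points_are_degenerate(self):
        cloud = np.array([[0.0, 0], [1, 1], [2, 2]])
        assert build_polytope(cloud, 0, np.array([1, 2])) is None

    def test_too_few_points(self):
        cloud = np.array([[0.0, 0], [1, 0], [0, 1]])
        assert build_polytope(cloud, 0, np.array([1])) is None

    def test_contains_matches_lp_oracle(self):
        rng = np.random.default_rng(7)
        cloud = rng.normal(size=(10, 3))
        poly = build_polytope(cloud, 0, np.arange(1, 10))
        queries = rng.normal(scale=1.5, size=(200, 3))
        mine = poly.contains(queries)
        oracle = np.array([lp_point_in_hull(poly.vertices, q) for q in queries])
        assert (mine == oracle).all()


class TestOccupancy:
    def _unit_square(self, shift=(0.0, 0.0)):
        cloud = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]]) + np.asarray(shift)
        return build_polytope(cloud, 0, np.array([1, 2, 3]))

    def test_unit_square_four_cells(self):
        grid = GridSpec(origin=(0.0, 0.0), grain=0.5, shape=(2, 2))
        hv = occupancy([self._unit_square()], grid)
        assert len(hv) == 4
        assert hv.volume == pytest.approx(1.0)

    def test_disjoint_squares_are_additive(self):
        grid = GridSpec(origin=(0.0, 0.0), grain=0.5, shape=(10, 2))
        hv = occupancy([self._unit_square(), self._unit_square((3.0, 0.0))], grid)
        assert len(hv) == 8

    def test_vertex_outside_grid_is_contract_violation(self):
        grid = GridSpec(origin=(0.0, 0.0), grain=0.5, shape=(2, 2))
        with pytest.raises(GridError):
            occupancy([self._unit_square((5.0, 0.0))], grid)

    def test_boundary_centroid_counts_as_inside(self):
        # square [0, 0.75]²; the centroid at (0.75, 0.75) sits exactly on its corner
        cloud = np.array([[0.0, 0], [0.75, 0], [0, 0.75], [0.75, 0.75]])
        poly = build_polytope(cloud, 0, np.array([1, 2, 3]))
        grid = GridSpec(origin=(-0.5, -0.5), grain=0.5, shape=(4, 4))
        hv = occupancy([poly], grid)
        centroids = hv.grid.centroids(hv.cells)
        assert any(np.allclose(c, [0.75, 0.75]) for c in centroids)

    def test_monte_carlo_oracle_random_3d_hulls(self):
        rng = np.random.default_rng(11)
        for _ in range(2):
            cloud = rng.uniform(0, 1, size=(14, 3))
            poly = build_polytope(cloud, 0, np.arange(1, 14))
            grid = GridSpec.from_points(cloud, grain=0.02)
            hv = occupancy([poly], grid)
            lo, hi = cloud.min(axis=0), cloud.max(axis=0)
            samples = rng.uniform(lo, hi, size=(100_000, 3))
            mc = poly.contains(samples).mean() * np.prod(hi - lo)
            assert hv.volume == pytest.approx(mc, rel=0.02)


class TestUnion:
    def _hv(self, grid, cells):
        return Hypervolume(grid, frozenset(cells))

    def test_idempotent(self):
        grid = GridSpec((0.0,) * 2, 1.0, (5, 5))
        hv = self._hv(grid, {1, 2, 3})
        out = union_volume([hv, hv, hv])
        assert out.cells == hv.cells

    def test_disjoint_sets_add(self):
        grid = GridSpec((0.0,) * 2, 1.0, (5, 5))
        out = union_volume([self._hv(grid, {0, 1, 2}), self._hv(grid, {10, 11, 12, 13})])
        assert len(out) == 7

    def test_subadditive(self):
        rng = np.random.default_rng(1)
        grid = GridSpec((0.0,) * 2, 1.0, (10, 10))
        hvs = [self._hv(grid, set(rng.integers(0, 100, 20).tolist())) for _ in range(4)]
        assert union_volume(hvs).volume <= sum(h.volume for h in hvs) + 1e-12

    def test_mismatched_grids_rejected(self):
        a = self._hv(GridSpec((0.0, 0.0), 1.0, (5, 5)), {1})
        b = self._hv(GridSpec((0.0, 0.0), 2.0, (5, 5)), {1})
        with pytest.raises(GridError):
            union_volume([a, b])


class TestIndividualHypervolume:
    def test_identical_points_give_empty_hypervolume(self):
        cloud = np.ones((8, 2))
        grid = GridSpec((0.0, 0.0), 0.5, (5, 5))
        with pytest.warns(UserWarning, match="no valid polytope"):
            hv = individual_hypervolume(cloud, LocohParams(a=10.0, d=2), grid)
        assert len(hv) == 0
        assert hv.n_points_ignored == 8

    def test_volume_monotone_in_a_with_nested_cells(self):
        rng = np.random.default_rng(21)
        cloud = rng.normal(size=(40, 2))
        grid = GridSpec.from_points(cloud, 0.1)
        prev = None
        for a in (0.5, 1.0, 2.0, 4.0, 8.0):
            hv = individual_hypervolume(cloud, LocohParams(a=a, d=2), grid)
            if prev is not None:
                assert prev.cells <= hv.cells  # nestedness, not just volume
            prev = hv

    def test_infinite_a_equals_global_hull(self):
        rng = np.random.default_rng(5)
        cloud = rng.normal(size=(15, 3))
        grid = GridSpec.from_points(cloud, 0.15)
        hv = individual_hypervolume(cloud, LocohParams(a=np.inf, d=3), grid)
        whole = build_polytope(cloud, 0, np.arange(1, 15))
        global_hv = occupancy([whole], grid)
        assert hv.cells == global_hv.cells

    def test_strict_rule_ignores_more_points(self):
        rng = np.random.default_rng(9)
        cloud = rng.normal(size=(25, 2))
        params = LocohParams(a=0.6, d=2)
        _, loose, strict_count = local_polytopes(cloud, params, strict=False)
        _, strict, _ = local_polytopes(cloud, params, strict=True)
        assert strict >= loose
        assert strict >= strict_count  # every short-of-neighbours point is out

    def test_individual_subset_of_union(self, specialist_dataset):
        from misi import foraging_points, individual_hypervolumes, union_volume

        pts = foraging_points(specialist_dataset)
        params = LocohParams(a=400_000.0, d=2)
        grid = GridSpec.from_points(pts[["c0", "c1"]].to_numpy(), 25_000.0)
        hvs = individual_hypervolumes(pts, params, grid)
        total = union_volume(list(hvs.values()))
        for hv in hvs.values():
            assert hv.cells <= total.cells

    def test_polytope_areas_match_shoelace(self):
        rng = np.random.default_rng(13)
        cloud = rng.uniform(0, 5, size=(30, 2))
        polys, _, _ = local_polytopes(cloud, LocohParams(a=4.0, d=2))
        assert polys
        for poly in polys:
            assert poly.measure == pytest.approx(shoelace(poly.vertices), rel=1e-9)
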