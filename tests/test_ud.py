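import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelagos import ud
from pelagos.ud import (
    GridSpec,
    SmoothingSpec,
    UDGrid,
    bhattacharyya,
    individual_core_areas,
    isopleth,
    kde_ud,
    make_grid,
    population_ud,
    representativeness,
    segregation_test,
)


def random_ud(rng, n=6):
    p = rng.random((n, n)) + 1e-12
    p /= p.sum()
    return UDGrid(GridSpec(0.0, 0.0, n, n, 10.0), p)


class TestKde:
    def test_single_fix_unimodal_and_normalized(self):
        grid = make_grid([0.0], [0.0], 60.0, 10.0)
        u = kde_ud([0.0], [0.0], 60.0, grid)
        assert u.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        iy, ix = np.unravel_index(np.argmax(u.pmf), u.pmf.shape)
        ixf, iyf = grid.index_of(0.0, 0.0)
        assert (ix, iy) == (int(ixf), int(iyf))

    def test_coincident_fixes_equal_single_fix(self):
        grid = make_grid([0.0], [0.0], 60.0, 10.0)
        u1 = kde_ud([0.0], [0.0], 60.0, grid)
        u2 = kde_ud([0.0, 0.0], [0.0, 0.0], 60.0, grid)
        assert np.allclose(u1.pmf, u2.pmf)

    def test_half_mass_radius_of_gaussian_kernel(self):
        # a circular Gaussian holds 50% of its mass within 1.1774 sigma
        h = 105.0
        grid = make_grid([0.0], [0.0], h, 10.0)
        u = kde_ud([0.0], [0.0], h, grid)
        xc, yc = grid.centers()
        X, Y = np.meshgrid(xc, yc)
        frac = u.pmf[np.hypot(X, Y) <= 1.1774 * h].sum()
        assert frac == pytest.approx(0.50, abs=0.02)

    def test_auto_expand_warns_and_covers(self):
        grid = GridSpec(-50.0, -50.0, 10, 10, 10.0)
        with pytest.warns(UserWarning, match="expand"):
            u = kde_ud([500.0], [0.0], 60.0, grid)
        assert u.pmf.sum() == pytest.approx(1.0, abs=1e-9)


class TestPopulationUD:
    def test_single_trip_is_identity(self):
        rng = np.random.default_rng(0)
        u = random_ud(rng)
        assert np.allclose(population_ud([u]).pmf, u.pmf)

    def test_two_identical(self):
        rng = np.random.default_rng(1)
        u = random_ud(rng)
        assert np.allclose(population_ud([u, u]).pmf, u.pmf)

    def test_disjoint_point_masses_average(self):
        g = GridSpec(0.0, 0.0, 2, 1, 10.0)
        a = UDGrid(g, np.array([[1.0, 0.0]]))
        b = UDGrid(g, np.array([[0.0, 1.0]]))
        assert np.allclose(population_ud([a, b]).pmf, [[0.5, 0.5]])


class TestIsopleth:
    def test_uniform_four_cells(self):
        g = GridSpec(0.0, 0.0, 2, 2, 10.0)
        u = UDGrid(g, np.full((2, 2), 0.25))
        m = isopleth(u, 0.5)
        assert m.mask.sum() == 2

    def test_point_mass_single_cell(self):
        g = GridSpec(0.0, 0.0, 3, 3, 10.0)
        p = np.zeros((3, 3))
        p[1, 1] = 1.0
        for level in (0.05, 0.5, 0.95):
            assert isopleth(UDGrid(g, p), level).mask.sum() == 1

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_contained_mass_bound_and_minimality(self, seed):
        rng = np.random.default_rng(seed)
        u = random_ud(rng)
        level = float(rng.uniform(0.05, 0.95))
        m = isopleth(u, level)
        assert level <= m.contained_mass <= level + u.pmf.max() + 1e-12
        # removing the smallest selected cell drops below the level
        sel = u.pmf[m.mask]
        assert m.contained_mass - sel.min() < level


class TestBhattacharyya:
    def test_identical_is_one(self):
        rng = np.random.default_rng(2)
        u = random_ud(rng)
        assert bhattacharyya(u, u) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_is_zero(self):
        g = GridSpec(0.0, 0.0, 2, 1, 10.0)
        a = UDGrid(g, np.array([[1.0, 0.0]]))
        b = UDGrid(g, np.array([[0.0, 1.0]]))
        assert bhattacharyya(a, b) == 0.0

    def test_two_cell_hand_value(self):
        # sqrt(.5*.25) + sqrt(.5*.75) = 0.9659258...
        got = bhattacharyya(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        assert got == pytest.approx(
            np.sqrt(0.125) + np.sqrt(0.375), abs=1e-12
        )
        assert got == pytest.approx(0.9659, abs=1e-4)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_bounds_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_ud(rng), random_ud(rng)
        ba = bhattacharyya(a, b)
        assert 0.0 <= ba <= 1.0 + 1e-12
        assert ba == pytest.approx(bhattacharyya(b, a), abs=1e-12)
        perm = rng.permutation(a.pmf.size)
        assert bhattacharyya(
            a.pmf.ravel()[perm], b.pmf.ravel()[perm]
        ) == pytest.approx(ba, abs=1e-12)


class TestSegregationTest:
    def make_uds(self, rng, n, shift=0.0):
        g = make_grid([-120.0, 240.0], [-60.0, 180.0], 20.0, 10.0)
        out = []
        for _ in range(n):
            x = rng.normal(30 + shift, 15, 20)
            y = rng.normal(60, 15, 20)
            out.append(kde_ud(np.clip(x, -110, 230), np.clip(y, -50, 170), 20.0, g))
        return out

    def test_observed_ba_matches_population_uds(self):
        rng = np.random.default_rng(3)
        a, b = self.make_uds(rng, 5), self.make_uds(rng, 7, shift=40.0)
        res = segregation_test(a, b, n_iter=100, seed=0)
        expected = bhattacharyya(population_ud(a), population_ud(b))
        assert res.observed_ba == pytest.approx(expected, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        a, b = self.make_uds(rng, 4), self.make_uds(rng, 4)
        r1 = segregation_test(a, b, n_iter=50, seed=11)
        r2 = segregation_test(a, b, n_iter=50, seed=11)
        assert np.array_equal(r1.null_ba, r2.null_ba)
        assert r1.p_value == r2.p_value

    def test_requires_two_trips_per_group(self):
        rng = np.random.default_rng(5)
        a, b = self.make_uds(rng, 1), self.make_uds(rng, 4)
        with pytest.raises(ValueError):
            segregation_test(a, b, n_iter=100)

    def test_plus_one_variant(self):
        rng = np.random.default_rng(6)
        a, b = self.make_uds(rng, 4), self.make_uds(rng, 4, shift=80.0)
        r = segregation_test(a, b, n_iter=100, seed=0, plus_one=True)
        assert r.p_value >= 1.0 / 101.0

    def test_isopleth_restricted_ba_is_smaller_or_equal_support(self):
        rng = np.random.default_rng(7)
        a, b = self.make_uds(rng, 5), self.make_uds(rng, 5, shift=60.0)
        full = segregation_test(a, b, n_iter=50, seed=1)
        core = segregation_test(a, b, n_iter=50, seed=1, isopleth_level=0.5)
        assert 0.0 <= core.observed_ba <= 1.0
        assert core.isopleth_level == 0.5
        assert full.isopleth_level is None


class TestRepresentativeness:
    def test_identical_trips_saturate(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 50, (30, 2))
        trips = [(pts[:, 0], pts[:, 1])] * 8
        grid = make_grid(pts[:, 0], pts[:, 1], 60.0, 10.0)
        res = representativeness(trips, 60.0, grid, n_boot=10, seed=1)
        assert res.percent > 95.0

    def test_common_distribution_high_coverage(self):
        rng = np.random.default_rng(1)
        trips = []
        for _ in range(15):
            pts = rng.normal(0, 80, (25, 2))
            trips.append((pts[:, 0], pts[:, 1]))
        allx = np.concatenate([x for x, _ in trips])
        ally = np.concatenate([y for _, y in trips])
        grid = make_grid(allx, ally, 60.0, 10.0)
        res = representativeness(trips, 60.0, grid, n_boot=20, seed=2)
        assert res.percent >= 90.0

    def test_two_trips_is_low_confidence(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 50, (20, 2))
        trips = [(pts[:, 0], pts[:, 1]), (pts[:, 0] + 5, pts[:, 1])]
        grid = make_grid(pts[:, 0], pts[:, 1], 60.0, 10.0)
        res = representativeness(trips, 60.0, grid, n_boot=5, seed=3)
        assert res.low_confidence
        assert 0.0 <= res.percent <= 100.0


class TestIndividualCoreAreas:
    def test_single_bird_single_trip_equals_trip_core(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 40, (20, 2))
        grid = make_grid(pts[:, 0], pts[:, 1], 60.0, 10.0)
        masks, counts = individual_core_areas(
            {"b1": [(pts[:, 0], pts[:, 1])]}, 60.0, grid
        )
        trip_core = isopleth(kde_ud(pts[:, 0], pts[:, 1], 60.0, grid), 0.5)
        assert np.array_equal(masks["b1"].mask, trip_core.mask)
        assert counts.max() == 1

    def test_bird_count_surface_identity(self):
        rng = np.random.default_rng(5)
        birds = {}
        for i in range(4):
            pts = rng.normal(i * 100, 40, (15, 2))
            birds[f"b{i}"] = [(pts[:, 0], pts[:, 1])]
        allx = np.concatenate([xy[0][0] for xy in birds.values()])
        ally = np.concatenate([xy[0][1] for xy in birds.values()])
        grid = make_grid(allx, ally, 60.0, 10.0)
        masks, counts = individual_core_areas(birds, 60.0, grid)
        assert counts.sum() == sum(m.mask.sum() for m in masks.values())


class TestSmoothingSpec:
    def test_stage_bandwidths(self):
        spec = SmoothingSpec()
        assert spec.for_stage("incubation") == 105.0
        assert spec.for_stage("brood_guard") == 60.0
        assert spec.for_stage("postguard") == 105.0
        assert spec.cell_km == 10.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            SmoothingSpec(cell_km=0.0)
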