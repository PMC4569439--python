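"""Diversity indices and marked summary functions against brute-force oracles.

Every pairwise quantity is checked against O(n^2) double loops on random
patterns; the CSR benchmarks (K ~ pi r^2, G/F ~ 1 - exp(-lambda pi r^2),
J ~ 1) are exercised at reduced replication here and at full replication
in the acceptance suite.
"""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from habitat_ppa import (FEATURE_NAMES, RGrid, default_rgrid, empty_space_F,
                         extract_features, global_shannon, global_simpson,
                         inhomogeneous_F, isar_curve, local_shannon_curve,
                         local_simpson_curve, marked_G, marked_J, marked_K,
                         mci_curve, mingling_curve, neighbor_counts,
                         summarize_curve)
from habitat_ppa.spatial_map import MARKS

from conftest import csr_pattern, make_pattern


# ---------------------------------------------------------------------------
# Neighbor counts (closed r-ball, 0 < d <= r)

class TestNeighborCounts:
    def test_two_points_r_below_distance(self):
        p = make_pattern([(0, 0), (5, 0)], ["T1low", "T1high"],
                         window=(0, 6, 0, 6))
        nc = neighbor_counts(p, 4.0)
        assert list(nc.delta) == [0, 0]

    def test_boundary_radius_inclusive(self):
        p = make_pattern([(0, 0), (5, 0)], ["T1low", "T1high"],
                         window=(0, 6, 0, 6))
        nc = neighbor_counts(p, 5.0)
        assert list(nc.delta) == [1, 1]
        assert list(nc.delta_same) == [0, 0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_patterns(self, seed):
        rng = np.random.default_rng(seed)
        p = csr_pattern(50, rng)
        for r in default_rgrid(p).radii[::7]:
            nc = neighbor_counts(p, r)
            for i in range(p.n_points):
                delta = delta_same = 0
                by_mark = dict.fromkeys(MARKS, 0)
                for j in range(p.n_points):
                    if i == j:
                        continue
                    d = math.dist(p.points[i], p.points[j])
                    if 0 < d <= r:
                        delta += 1
                        by_mark[p.marks[j]] += 1
                        if p.marks[j] == p.marks[i]:
                            delta_same += 1
                assert nc.delta[i] == delta
                assert nc.delta_same[i] == delta_same
                assert list(nc.delta_by_mark[i]) == [by_mark[m] for m in MARKS]

    def test_counts_decompose_by_mark(self):
        rng = np.random.default_rng(9)
        p = csr_pattern(40, rng)
        nc = neighbor_counts(p, 0.2)
        assert np.array_equal(nc.delta_by_mark.sum(axis=1), nc.delta)


# ---------------------------------------------------------------------------
# Diversity indices

class TestMingling:
    def test_single_mark_pattern_is_zero(self):
        rng = np.random.default_rng(0)
        p = csr_pattern(30, rng, marks=("T1low",))
        c = mingling_curve(p, default_rgrid(p))
        defined = c.values[np.isfinite(c.values)]
        assert np.all(defined == 0.0)

    def test_two_points_different_marks(self):
        p = make_pattern([(0, 0), (1, 0)], ["T1low", "T2high"],
                         window=(0, 2, 0, 2))
        c = mingling_curve(p, RGrid(np.array([0.5, 1.0, 1.5])))
        assert np.isnan(c.values[0])  # no neighbors at r = 0.5
        assert c.values[1] == 1.0 and c.values[2] == 1.0

    def test_alternating_lattice_full_mingling(self):
        pts = [(i, 0) for i in range(10)]
        marks = ["T1low" if i % 2 == 0 else "T1high" for i in range(10)]
        p = make_pattern(pts, marks, window=(0, 9, 0, 1))
        c = mingling_curve(p, RGrid(np.array([1.0])))
        assert c.values[0] == 1.0

    def test_range_invariant(self):
        rng = np.random.default_rng(3)
        p = csr_pattern(60, rng)
        c = mingling_curve(p, default_rgrid(p))
        d = c.values[np.isfinite(c.values)]
        assert np.all((d >= 0) & (d <= 1))


class TestShannonSimpson:
    def test_uniform_four_mark_neighborhood(self):
        # focal point at the center of 4 equidistant neighbors, one per mark
        pts = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]
        marks = ["T1low", "T1low", "T1high", "T2low", "T2high"]
        p = make_pattern(pts, marks, window=(-1, 1, -1, 1))
        rg = RGrid(np.array([1.0]))
        h = local_shannon_curve(p, rg)
        # the center point sees all four marks equally
        nc = neighbor_counts(p, 1.0)
        i = 0
        probs = nc.delta_by_mark[i] / nc.delta[i]
        assert np.isclose(-(probs * np.log(probs)).sum(), math.log(4))

    def test_global_indices_uniform_and_degenerate(self):
        rng = np.random.default_rng(0)
        p = make_pattern([(0, 0), (1, 0), (0, 1), (1, 1)], list(MARKS))
        assert np.isclose(global_shannon(p), math.log(4))
        assert np.isclose(global_simpson(p), 0.75)
        q = csr_pattern(10, rng, marks=("T2low",))
        assert global_shannon(q) == 0.0 and global_simpson(q) == 0.0

    def test_global_shannon_2110_abundances(self):
        pts = [(i, 0) for i in range(4)]
        p = make_pattern(pts, ["T1low", "T1low", "T1high", "T2low"],
                         window=(0, 3, 0, 1))
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert np.isclose(global_shannon(p), expected)
        assert np.isclose(expected, 1.0397, atol=1e-4)

    @pytest.mark.parametrize("seed", range(3))
    def test_local_curves_match_per_point_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = csr_pattern(25, rng)
        r = 0.3
        h = local_shannon_curve(p, RGrid(np.array([r]))).values[0]
        s = local_simpson_curve(p, RGrid(np.array([r]))).values[0]
        hs, ss = [], []
        for i in range(p.n_points):
            counts = dict.fromkeys(MARKS, 0)
            for j in range(p.n_points):
                d = math.dist(p.points[i], p.points[j])
                if i != j and 0 < d <= r:
                    counts[p.marks[j]] += 1
            tot = sum(counts.values())
            if tot == 0:
                continue
            probs = [c / tot for c in counts.values() if c > 0]
            hs.append(-sum(q * math.log(q) for q in probs))
            ss.append(1 - sum(q * q for q in probs))
        assert np.isclose(h, np.mean(hs))
        assert np.isclose(s, np.mean(ss))

    def test_ranges(self):
        rng = np.random.default_rng(7)
        p = csr_pattern(80, rng)
        rg = default_rgrid(p)
        h = local_shannon_curve(p, rg).values
        s = local_simpson_curve(p, rg).values
        assert np.nanmax(h) <= math.log(4) + 1e-12 and np.nanmin(h) >= 0
        assert np.nanmax(s) <= 0.75 + 1e-12 and np.nanmin(s) >= 0


class TestIsar:
    def test_maximum_is_three(self):
        # all four marks co-located: every focal point finds the other 3
        pts = [(0.5, 0.5)] * 4
        p = make_pattern(pts, list(MARKS))
        c = isar_curve(p, RGrid(np.array([0.1])))
        assert c.values[0] == 3.0

    def test_single_mark_is_zero(self):
        rng = np.random.default_rng(1)
        p = csr_pattern(20, rng, marks=("T1high",))
        c = isar_curve(p, default_rgrid(p))
        assert np.all(c.values == 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_check(self, seed):
        rng = np.random.default_rng(seed)
        p = csr_pattern(30, rng)
        r = 0.25
        got = isar_curve(p, RGrid(np.array([r]))).values[0]
        present = [m for m, c in p.mark_counts().items() if c > 0]
        per_u = []
        for u in present:
            acc = 0.0
            xu = p.points[p.marks == u]
            for v in present:
                if v == u:
                    continue
                xv = p.points[p.marks == v]
                acc += np.mean([any(math.dist(x, y) <= r for y in xv)
                                for x in xu])
            per_u.append(acc)
        assert np.isclose(got, np.mean(per_u))


class TestMci:
    def test_single_mark_is_zero(self):
        rng = np.random.default_rng(2)
        p = csr_pattern(25, rng, marks=("T2high",))
        c = mci_curve(p, default_rgrid(p))
        defined = c.values[np.isfinite(c.values)]
        assert np.allclose(defined, 0.0)

    def test_matches_direct_formula_on_small_pattern(self):
        pts = [(0, 0), (1, 0), (0, 1), (1, 1)]
        marks = ["T1low", "T1high", "T1low", "T2low"]
        p = make_pattern(pts, marks, window=(0, 1, 0, 1))
        r = 1.0
        got = mci_curve(p, RGrid(np.array([r]))).values[0]
        pg = {m: list(marks).count(m) / 4 for m in set(marks)}
        cis = []
        for i in range(4):
            counts = {}
            for j in range(4):
                d = math.dist(pts[i], pts[j])
                if i != j and 0 < d <= r:
                    counts[marks[j]] = counts.get(marks[j], 0) + 1
            delta = sum(counts.values())
            if delta == 0:
                continue
            logpmf = math.lgamma(delta + 1)
            for m, k in counts.items():
                logpmf += -math.lgamma(k + 1) + k * math.log(pg[m])
            cis.append(-logpmf / delta)
        assert np.isclose(got, np.mean(cis))

    def test_proportional_composition_minimizes_ci(self):
        # over all compositions of delta = 6 into 4 parts, the composition
        # closest to the global proportions attains the minimal CI
        from itertools import product
        pg = np.array([0.5, 1 / 6, 1 / 6, 1 / 6])
        delta = 6
        best, best_ci = None, np.inf
        for ks in product(range(delta + 1), repeat=4):
            if sum(ks) != delta:
                continue
            k = np.array(ks, dtype=float)
            logpmf = (gammaln(delta + 1) - gammaln(k + 1).sum()
                      + (k * np.log(pg)).sum())
            ci = -logpmf / delta
            if ci < best_ci:
                best, best_ci = ks, ci
        assert best == (3, 1, 1, 1)  # = delta * pg


# ---------------------------------------------------------------------------
# Marked summary functions

class TestMarkedG:
    def test_single_step_cdf(self):
        p = make_pattern([(0, 0), (3, 0)], ["T1low", "T2low"],
                         window=(0, 4, 0, 4))
        c = marked_G(p, "T1low", "T2low", RGrid(np.array([1.0, 2.9, 3.0, 4.0])))
        assert list(c.values) == [0.0, 0.0, 1.0, 1.0]

    def test_missing_when_insufficient_points(self):
        p = make_pattern([(0, 0)], ["T1low"], window=(0, 1, 0, 1))
        c = marked_G(p, "T1low", "T2high", RGrid(np.array([0.5])))
        assert c.is_missing

    @pytest.mark.parametrize("seed", range(4))
    def test_cdf_properties_on_random_patterns(self, seed):
        rng = np.random.default_rng(seed)
        p = csr_pattern(60, rng)
        c = marked_G(p, "T1low", "T1high", default_rgrid(p))
        v = c.values[np.isfinite(c.values)]
        assert np.all((v >= 0) & (v <= 1))
        assert np.all(np.diff(v) >= 0)

    def test_same_mark_excludes_self(self):
        p = make_pattern([(0, 0), (1, 0), (2, 0)], ["T1low"] * 3,
                         window=(0, 2, 0, 1))
        c = marked_G(p, "T1low", "T1low", RGrid(np.array([0.5, 1.0])))
        assert c.values[1] == 1.0 and c.values[0] == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_nearest_neighbor_cdf_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = csr_pattern(50, rng)
        rg = default_rgrid(p)
        c = marked_G(p, "T2low", "T2high", rg)
        xu = p.points[p.marks == "T2low"]
        xv = p.points[p.marks == "T2high"]
        dmins = [min(math.dist(x, y) for y in xv) for x in xu]
        for k, r in enumerate(rg.radii):
            assert np.isclose(c.values[k],
                              np.mean([d <= r for d in dmins]))


class TestEmptySpaceF:
    def test_single_point_geometry(self):
        # one v-point at the window center: F(r) = fraction of lattice
        # locations within r, which approximates min(pi r^2, ...) geometry
        p = make_pattern([(0.5, 0.5)], ["T1low"])
        rg = RGrid(np.array([0.1, 0.25, 0.4]))
        c = empty_space_F(p, "T1low", rg, n_test=4096)
        from habitat_ppa.features import _test_lattice
        lattice = _test_lattice(p.window, 4096)
        d = np.hypot(lattice[:, 0] - 0.5, lattice[:, 1] - 0.5)
        for k, r in enumerate(rg.radii):
            assert np.isclose(c.values[k], (d <= r).mean())

    def test_cdf_range_and_monotone(self):
        rng = np.random.default_rng(5)
        p = csr_pattern(80, rng)
        c = empty_space_F(p, "T1low", default_rgrid(p))
        assert np.all((c.values >= 0) & (c.values <= 1))
        assert np.all(np.diff(c.values) >= 0)


class TestInhomogeneousF:
    def test_matches_plain_F_on_homogeneous_pattern(self):
        rng = np.random.default_rng(0)
        diffs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = csr_pattern(150, rng)
            rg = default_rgrid(p)
            # pooled plain empty-space: nearest point of any mark
            from habitat_ppa.features import _test_lattice
            from scipy.spatial import cKDTree
            lattice = _test_lattice(p.window, 1024)
            d, _ = cKDTree(p.points).query(lattice)
            plain = np.array([(d <= r).mean() for r in rg.radii])
            inhom = inhomogeneous_F(p, rg, bandwidth=0.25).values
            diffs.append(np.max(np.abs(plain - inhom)))
        assert np.mean(diffs) < 0.05

    def test_single_point_contact_cdf(self):
        p = make_pattern([(0.5, 0.5)], ["T1low"])
        rg = RGrid(np.array([0.2, 0.45]))
        c = inhomogeneous_F(p, rg, bandwidth=0.2)
        plain = empty_space_F(p, "T1low", rg)
        assert np.allclose(c.values, plain.values)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(11)
        p = csr_pattern(100, rng)
        c = inhomogeneous_F(p, default_rgrid(p), bandwidth=0.2)
        assert np.all((c.values >= 0) & (c.values <= 1 + 1e-12))


class TestMarkedK:
    def test_zero_below_minimum_distance(self):
        p = make_pattern([(0, 0), (1, 0)], ["T1low", "T2low"],
                         window=(0, 1, 0, 1))
        c = marked_K(p, "T1low", "T2low", RGrid(np.array([0.5])))
        assert c.values[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(200 + seed)
        p = csr_pattern(50, rng)
        rg = default_rgrid(p)
        u, v = "T1high", "T2low"
        c = marked_K(p, u, v, rg)
        xu = p.points[p.marks == u]
        xv = p.points[p.marks == v]
        area = p.window_area
        for k, r in enumerate(rg.radii[::5]):
            count = sum(1 for x in xu for y in xv if math.dist(x, y) <= r)
            expected = area / (len(xu) * len(xv)) * count
            assert np.isclose(c.values[np.where(rg.radii == r)[0][0]],
                              expected)

    def test_nonnegative_nondecreasing(self):
        rng = np.random.default_rng(6)
        p = csr_pattern(70, rng)
        c = marked_K(p, "T1low", "T1high", default_rgrid(p))
        assert np.all(c.values >= 0) and np.all(np.diff(c.values) >= 0)


class TestMarkedJ:
    def test_undefined_where_F_is_one(self):
        # dense v-points: F saturates at 1 -> J missing there, not infinite
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(0, 1, 500),
                               rng.uniform(0, 1, 500)])
        p = make_pattern(pts, ["T2low"] * 499 + ["T1low"])
        rg = RGrid(np.array([0.02, 0.5]))
        c = marked_J(p, "T1low", "T2low", rg)
        assert np.isnan(c.values[1])  # F = 1 at r = 0.5

    def test_clustered_marks_give_small_J(self):
        # v tightly clustered around u points -> G rises fast, J < 1
        rng = np.random.default_rng(4)
        centers = np.column_stack([rng.uniform(0.2, 0.8, 10),
                                   rng.uniform(0.2, 0.8, 10)])
        sat = np.repeat(centers, 5, axis=0) + rng.normal(0, 0.01, (50, 2))
        pts = np.vstack([centers, sat])
        marks = ["T1low"] * 10 + ["T1high"] * 50
        p = make_pattern(pts, marks)
        rg = RGrid(np.array([0.05]))
        c = marked_J(p, "T1low", "T1high", rg)
        assert c.values[0] < 1.0


class TestSummarizeCurve:
    def test_constant_curve(self):
        from habitat_ppa import SummaryCurve
        c = SummaryCurve(np.arange(1.0, 6.0), np.full(5, 3.25), "K")
        assert summarize_curve(c) == (3.25, 0.0)

    def test_two_point_sd(self):
        from habitat_ppa import SummaryCurve
        c = SummaryCurve(np.array([1.0, 2.0]), np.array([0.0, 1.0]), "G")
        mean, sd = summarize_curve(c)
        assert mean == 0.5 and np.isclose(sd, math.sqrt(0.5))

    def test_missing_radii_excluded(self):
        from habitat_ppa import SummaryCurve
        c = SummaryCurve(np.arange(1.0, 5.0),
                         np.array([np.nan, 2.0, np.nan, 4.0]), "J")
        mean, sd = summarize_curve(c)
        assert mean == 3.0 and np.isclose(sd, math.sqrt(2.0))

    def test_fewer_than_two_defined_is_missing(self):
        from habitat_ppa import SummaryCurve
        c = SummaryCurve(np.array([1.0, 2.0]), np.array([np.nan, 1.0]), "F")
        assert all(math.isnan(v) for v in summarize_curve(c))


# ---------------------------------------------------------------------------
# Assembled feature vector

class TestExtractFeatures:
    def test_exactly_27_named_features(self):
        rng = np.random.default_rng(0)
        p = csr_pattern(100, rng)
        fv = extract_features(p)
        assert list(fv.values.index) == list(FEATURE_NAMES)
        assert len(fv.values) == 27
        assert fv.values.notna().all()

    def test_single_mark_pattern_contract(self):
        rng = np.random.default_rng(1)
        p = csr_pattern(40, rng, marks=("T1low",))
        fv = extract_features(p)
        assert len(fv.values) == 27
        assert fv.values["Shannon index"] == 0.0
        assert fv.values["Simpson index"] == 0.0
        assert fv.values["ISAR"] == 0.0
        assert math.isnan(fv.values["Mean K"])
        assert math.isnan(fv.values["Mean G for T1 and T2"])
        assert "missing" in fv.diagnostics

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = csr_pattern(80, rng)
        perm = rng.permutation(p.n_points)
        q = make_pattern(p.points[perm], p.marks[perm], window=p.window)
        a = extract_features(p).values
        b = extract_features(q).values
        assert np.allclose(a, b, equal_nan=True)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        p = csr_pattern(80, rng)
        shift = np.array([13.0, -4.0])
        xmin, xmax, ymin, ymax = p.window
        q = make_pattern(p.points + shift, p.marks,
                         window=(xmin + 13, xmax + 13, ymin - 4, ymax - 4))
        a = extract_features(p).values
        b = extract_features(q).values
        assert np.allclose(a, b, equal_nan=True)

    def test_degenerate_below_two_points(self):
        p = make_pattern([(0.5, 0.5)], ["T1low"])
        fv = extract_features(p)
        assert len(fv.values) == 27 and fv.values.isna().all()
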