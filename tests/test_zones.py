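"""Zone geometry, kernel density, natural breaks and overlap splitting."""

import itertools

import numpy as np
import pytest
import shapely
from shapely.geometry import Point, Polygon, box

from zonecast import (
    DissolvedZone,
    build_zones,
    classify_and_dissolve,
    clip_and_dedupe,
    count_in_zones,
    kde_surface,
    natural_breaks,
    split_overlaps,
)


def mc_area(geom, bounds, n=100_000, seed=0):
    """Monte-Carlo point-in-polygon area oracle."""
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = bounds
    pts = rng.uniform((minx, miny), (maxx, maxy), size=(n, 2))
    frac = shapely.intersects(shapely.points(pts), geom).mean()
    box_area = (maxx - minx) * (maxy - miny)
    return frac * box_area, box_area * np.sqrt(frac * (1 - frac) / n)


class TestBuildZones:
    def test_minkowski_area_of_square_school(self):
        school = box(0, 0, 100, 100)
        [zone] = build_zones({"s": school}, 400.0)
        expected = 100**2 + 4 * 100 * 400 + np.pi * 400**2
        assert zone.geometry.area == pytest.approx(expected, rel=0.005)
        assert school.within(zone.geometry)

    def test_zero_distance_identity(self):
        school = box(0, 0, 50, 80)
        [zone] = build_zones({"s": school}, 0.0)
        assert zone.geometry.symmetric_difference(school).area < 1e-6

    def test_distant_schools_give_disjoint_zones(self):
        zones = build_zones({"a": box(0, 0, 100, 100), "b": box(2000, 0, 2100, 100)}, 400.0)
        assert not zones[0].geometry.intersects(zones[1].geometry)

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError, match="bad_school"):
            build_zones({"bad_school": Polygon()}, 400.0)


class TestClipAndDedupe:
    def test_identical_zones_union_once(self):
        zones = build_zones({"a": box(0, 0, 100, 100), "b": box(0, 0, 100, 100)}, 200.0)
        union = clip_and_dedupe(zones, box(-1000, -1000, 2000, 2000))
        assert union.area == pytest.approx(zones[0].geometry.area, rel=1e-9)

    def test_half_outside_boundary_monte_carlo(self):
        zones = build_zones({"a": box(-100, -100, 100, 100)}, 300.0)
        boundary = box(0, -5000, 5000, 5000)  # clips the left half exactly
        clipped = clip_and_dedupe(zones, boundary)
        assert clipped.area == pytest.approx(zones[0].geometry.area / 2, rel=1e-6)
        est, se = mc_area(clipped, (-500, -500, 500, 500))
        assert abs(est - clipped.area) < 3 * se

    def test_disjoint_zones_add(self):
        zones = build_zones({"a": box(0, 0, 10, 10), "b": box(5000, 0, 5010, 10)}, 100.0)
        union = clip_and_dedupe(zones, box(-1000, -1000, 9000, 9000))
        assert union.area == pytest.approx(sum(z.geometry.area for z in zones), rel=1e-9)

    def test_no_intersection_warns_empty(self):
        zones = build_zones({"a": box(0, 0, 10, 10)}, 10.0)
        with pytest.warns(UserWarning, match="boundary"):
            out = clip_and_dedupe(zones, box(10000, 10000, 10010, 10010))
        assert out.is_empty


class TestCountInZones:
    def test_empty_and_full(self):
        geom = box(0, 0, 10, 10)
        assert count_in_zones(np.empty((0, 2)), geom) == 0
        pts = np.random.default_rng(0).uniform(1, 9, (50, 2))
        assert count_in_zones(pts, geom) == 50

    def test_boundary_points_count(self):
        geom = box(0, 0, 10, 10)
        assert count_in_zones([[0.0, 5.0], [10.0, 10.0]], geom) == 2

    def test_brute_force_circle_oracle(self, rng):
        circle = Point(0, 0).buffer(3.0, quad_segs=64)
        pts = rng.uniform(-5, 5, (1000, 2))
        brute = sum(circle.covers(Point(x, y)) for x, y in pts)
        assert count_in_zones(pts, circle) == brute


class TestKdeSurface:
    boundary = box(0, 0, 4000, 4000)

    def test_single_point_mass_and_peak(self):
        surf = kde_surface(np.array([[2050.0, 2050.0]]), 100.0, 500.0, self.boundary)
        assert surf.total_mass() == pytest.approx(1.0, rel=0.01)
        iy, ix = np.unravel_index(np.argmax(surf.values), surf.values.shape)
        assert surf.value_at(2050.0, 2050.0) == surf.values[iy, ix]

    def test_linearity_for_coincident_points(self):
        one = kde_surface(np.array([[1000.0, 1000.0]]), 100.0, 400.0, self.boundary)
        two = kde_surface(np.array([[1000.0, 1000.0]] * 2), 100.0, 400.0, self.boundary)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)

    def test_context_distance_rule(self):
        # 1.9 km beyond the boundary contributes, 2.1 km does not
        inside = np.array([[2000.0, 2000.0]])
        near = np.array([[2000.0, -1900.0]])
        far = np.array([[2000.0, -2100.0]])
        s_near = kde_surface(np.vstack([inside, near]), 100.0, 500.0, self.boundary)
        s_far = kde_surface(np.vstack([inside, far]), 100.0, 500.0, self.boundary)
        assert s_near.total_mass() == pytest.approx(2.0, rel=0.01)
        assert s_far.total_mass() == pytest.approx(1.0, rel=0.01)

    def test_mass_equals_point_count(self, rng):
        pts = rng.uniform(500, 3500, (40, 2))
        surf = kde_surface(pts, 100.0, 400.0, self.boundary)
        assert surf.total_mass() == pytest.approx(40.0, rel=0.01)

    def test_zero_points_warns(self):
        with pytest.warns(UserWarning, match="zero density"):
            surf = kde_surface(np.empty((0, 2)), 100.0, 500.0, self.boundary)
        assert surf.values.sum() == 0

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            kde_surface(np.array([[1.0, 1.0]]), 100.0, 50.0, self.boundary)


class TestNaturalBreaks:
    def exhaustive_sse(self, values, k):
        v = np.sort(values)
        n = len(v)

        def sse(seg):
            return ((seg - seg.mean()) ** 2).sum()

        best = np.inf
        for cuts in itertools.combinations(range(1, n), k - 1):
            idx = [0, *cuts, n]
            total = sum(sse(v[idx[i] : idx[i + 1]]) for i in range(k))
            best = min(best, total)
        return best

    def jenks_sse(self, values, thresholds):
        v = np.asarray(values, dtype=float)
        labels = np.searchsorted(thresholds, v, side="left")
        return sum(((v[labels == c] - v[labels == c].mean()) ** 2).sum() for c in np.unique(labels))

    def test_three_obvious_groups(self):
        thr = natural_breaks([1, 1, 1, 5, 5, 5, 10, 10, 10], k=3)
        assert len(thr) == 2 and thr[0] < 5 <= thr[1] < 10
        assert self.jenks_sse([1, 1, 1, 5, 5, 5, 10, 10, 10], thr) == 0

    def test_matches_exhaustive_partition(self, rng):
        values = rng.uniform(0, 100, 20)
        thr = natural_breaks(values, k=3)
        assert self.jenks_sse(values, thr) == pytest.approx(self.exhaustive_sse(values, 3), abs=1e-9)

    def test_exhaustive_agreement_property(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(derandomize=True, max_examples=30, deadline=None)
        @given(
            values=st.lists(
                st.floats(0, 1000, allow_nan=False), min_size=5, max_size=25, unique=True
            )
        )
        def check(values):
            thr = natural_breaks(values, k=3)
            assert self.jenks_sse(values, thr) == pytest.approx(
                self.exhaustive_sse(np.asarray(values), 3), abs=1e-6
            )

        check()

    def test_single_class_no_thresholds(self):
        assert natural_breaks([3, 1, 2], k=1).size == 0

    def test_insufficient_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            natural_breaks([1, 1, 2, 2], k=3)


def make_surface_from_points(points, boundary):
    return kde_surface(np.asarray(points, dtype=float), 100.0, 800.0, boundary)


class TestClassifyAndDissolve:
    boundary = box(0, 0, 6000, 6000)

    def test_all_one_class_equals_union(self, rng):
        schools = {f"s{i}": box(x, y, x + 100, y + 100) for i, (x, y) in enumerate([(500, 500), (5000, 5000)])}
        zones = build_zones(schools, 400.0)
        # uniform scatter far from both schools: both sites read the same class
        pts = rng.uniform(2500, 3500, (30, 2))
        surf = make_surface_from_points(pts, self.boundary)
        out = classify_and_dissolve(zones, surf, self.boundary, schools=schools)
        assert len(out) == 1
        union = clip_and_dedupe(zones, self.boundary)
        assert out[0].geometry.symmetric_difference(union).area < 1e-6

    def test_dense_cluster_school_classified_high(self, rng):
        schools = {
            "hot": box(950, 950, 1050, 1050),
            "cold": box(4950, 4950, 5050, 5050),
            "warm": box(2950, 2950, 3050, 3050),
        }
        zones = build_zones(schools, 400.0)
        pts = np.vstack(
            [
                rng.normal(1000, 150, (60, 2)),
                rng.normal(3000, 150, (12, 2)),
                rng.uniform(0, 6000, (5, 2)),
            ]
        )
        surf = make_surface_from_points(pts, self.boundary)
        out = classify_and_dissolve(zones, surf, self.boundary, schools=schools)
        by_label = {z.class_label: z for z in out}
        assert "high" in by_label
        assert by_label["high"].geometry.contains(schools["hot"].representative_point())

    def test_school_off_grid_rejected(self, rng):
        schools = {"away": box(90000, 90000, 90100, 90100)}
        zones = build_zones(schools, 400.0)
        surf = make_surface_from_points(rng.uniform(0, 6000, (30, 2)), self.boundary)
        with pytest.raises(ValueError, match="away"):
            classify_and_dissolve(zones, surf, self.boundary, schools=schools)


class TestSplitOverlaps:
    def test_no_overlap_is_identity(self):
        zones = [
            DissolvedZone("low", box(0, 0, 100, 100)),
            DissolvedZone("high", box(500, 500, 600, 600)),
        ]
        out = split_overlaps(zones)
        assert [z.class_label for z in out] == ["low", "high"]
        for a, b in zip(zones, out):
            assert a.geometry.symmetric_difference(b.geometry).area < 1e-9

    def test_equal_discs_split_by_bisector(self):
        a = Point(0, 0).buffer(500, quad_segs=64)
        b = Point(600, 0).buffer(500, quad_segs=64)
        out = split_overlaps([DissolvedZone("low", a), DissolvedZone("high", b)], cell=5.0)
        lens = a.intersection(b)
        got_a = out[0].geometry.intersection(lens).area
        got_b = out[1].geometry.intersection(lens).area
        assert got_a == pytest.approx(lens.area / 2, rel=0.01)
        assert got_b == pytest.approx(lens.area / 2, rel=0.01)
        # allocation respects the perpendicular bisector of the centres
        assert out[0].geometry.contains(Point(290, 0))
        assert out[1].geometry.contains(Point(310, 0))

    def test_nested_zone_keeps_geometry(self):
        inner = Point(0, 0).buffer(200, quad_segs=64)
        outer = Point(0, 0).buffer(800, quad_segs=64)
        out = split_overlaps([DissolvedZone("high", inner), DissolvedZone("low", outer)], cell=5.0)
        by_label = {z.class_label: z for z in out}
        assert by_label["high"].geometry.symmetric_difference(inner).area < 1e-6
        assert by_label["low"].geometry.intersection(inner).area < 1e-6

    def test_mutually_exclusive_and_union_preserved(self, rng):
        centres = rng.uniform(0, 2000, (4, 2))
        zones = [
            DissolvedZone(lbl, Point(*c).buffer(r, quad_segs=32))
            for lbl, c, r in zip(["low", "mid", "high", "low2"], centres, [500, 600, 450, 550])
        ]
        out = split_overlaps(zones, cell=10.0)
        union = shapely.unary_union([z.geometry for z in zones])
        total = sum(z.geometry.area for z in out)
        assert total == pytest.approx(union.area, rel=0.001)
        for z1, z2 in itertools.combinations(out, 2):
            assert z1.geometry.intersection(z2.geometry).area < 1e-6 * union.area
        est, se = mc_area(union, (-700, -700, 2700, 2700))
        assert abs(total - est) < 3 * se

    def test_count_conservation_after_split(self, rng):
        a = Point(0, 0).buffer(400, quad_segs=32)
        b = Point(300, 0).buffer(400, quad_segs=32)
        zones = [DissolvedZone("low", a), DissolvedZone("high", b)]
        out = split_overlaps(zones, cell=5.0)
        pts = rng.uniform(-500, 800, (400, 2))
        union = shapely.unary_union([a, b])
        split_total = sum(count_in_zones(pts, z.geometry) for z in out)
        assert split_total == count_in_zones(pts, union)
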