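"""Translational polarity: polygon geometry, vectors, deviation summaries."""

import math

import numpy as np
import pytest
from shapely.geometry import Polygon as ShapelyPolygon

from ciliapol.errors import (
    DegeneratePolygonError,
    InvalidParameterError,
    SelfIntersectingPolygonError,
)
from ciliapol.synthetic import gen_apical_map
from ciliapol.translational import (
    CellApicalMap,
    CellRecord,
    analyze_map,
    apical_area,
    polygon_centroid,
    summarize_translational,
    translational_vectors,
)


def random_convex_polygon(rng, n=8, scale=5.0):
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(0.5, 1.0, n) * scale
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


class TestPolygonGeometry:
    def test_unit_square_centroid_and_area(self, unit_square):
        assert polygon_centroid(unit_square) == pytest.approx((0.5, 0.5))
        assert apical_area(unit_square, pixel_size=1.0) == pytest.approx(1.0)

    def test_triangle_centroid_is_vertex_mean(self):
        assert polygon_centroid([(0, 0), (3, 0), (0, 3)]) == pytest.approx((1.0, 1.0))

    def test_triangle_area_with_calibration(self):
        # 2 px^2 at 0.5 um/px -> 0.5 um^2
        assert apical_area([(0, 0), (2, 0), (0, 2)], pixel_size=0.5) == pytest.approx(0.5)

    def test_vertex_order_does_not_change_results(self, unit_square):
        reversed_sq = list(reversed(unit_square))
        assert polygon_centroid(reversed_sq) == pytest.approx((0.5, 0.5))
        assert apical_area(reversed_sq, 1.0) == pytest.approx(1.0)

    def test_matches_shapely_on_random_convex_polygons(self, rng):
        for _ in range(20):
            poly = random_convex_polygon(rng)
            sh = ShapelyPolygon(poly)
            assert apical_area(poly, 1.0) == pytest.approx(sh.area, rel=1e-12)
            cx, cy = polygon_centroid(poly)
            assert (cx, cy) == pytest.approx((sh.centroid.x, sh.centroid.y), abs=1e-9)

    def test_centroid_matches_rejection_sampling(self, rng):
        poly = random_convex_polygon(rng, scale=1.0)
        sh = ShapelyPolygon(poly)
        minx, miny, maxx, maxy = sh.bounds
        pts = np.column_stack([
            rng.uniform(minx, maxx, 60_000), rng.uniform(miny, maxy, 60_000)
        ])
        from shapely import points as shapely_points, contains
        inside = pts[contains(sh, shapely_points(pts))]
        assert polygon_centroid(poly) == pytest.approx(tuple(inside.mean(axis=0)), abs=1e-2)

    def test_area_matches_rasterization(self):
        from skimage.draw import polygon as raster_polygon

        poly = np.array([(10.0, 5.0), (90.0, 12.0), (70.0, 80.0), (20.0, 60.0)])
        rr, cc = raster_polygon(poly[:, 1], poly[:, 0])
        assert apical_area(poly, 1.0) == pytest.approx(len(rr), rel=0.02)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(DegeneratePolygonError):
            polygon_centroid([(0, 0), (1, 1), (2, 2)])

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(SelfIntersectingPolygonError):
            apical_area(bowtie, 1.0)

    def test_tessellation_conserves_total_area(self):
        # 6x6 full grid: union of jittered quads is exactly the bounding rectangle
        cell_map, _ = gen_apical_map(
            n_cells=36, mean_area=25.0, area_cv=0.2, pixel_size=0.5, seed=11
        )
        total = sum(apical_area(c.polygon, cell_map.pixel_size) for c in cell_map.cells)
        side_px = math.sqrt(25.0) / 0.5
        bounding = (6 * side_px) ** 2 * 0.5**2
        assert total == pytest.approx(bounding, abs=1e-6)


class TestVectors:
    def make_map(self, bb, pixel_size=1.0):
        cell = CellRecord("c0", np.array([(-1, -1), (1, -1), (1, 1), (-1, 1)]), bb)
        return CellApicalMap("img", [cell], pixel_size)

    def test_angle_convention_positive_x(self):
        v = translational_vectors(self.make_map((1.0, 0.0)))[0]
        assert v.angle_deg == pytest.approx(0.0)
        assert v.magnitude_um == pytest.approx(1.0)

    def test_angle_convention_y_down_flips_to_270(self):
        # bb below centre in image coords (y down) -> 270 in math convention
        v = translational_vectors(self.make_map((0.0, 1.0)))[0]
        assert v.angle_deg == pytest.approx(270.0)

    def test_bb_at_centre_is_degenerate(self):
        v = translational_vectors(self.make_map((0.0, 0.0)))[0]
        assert v.degenerate and v.magnitude_um == pytest.approx(0.0)

    def test_missing_bb_skipped(self):
        cells = [
            CellRecord("a", np.array([(0, 0), (2, 0), (2, 2), (0, 2)]), (2.0, 1.0)),
            CellRecord("b", np.array([(3, 0), (5, 0), (5, 2), (3, 2)]), None),
        ]
        vectors = translational_vectors(CellApicalMap("img", cells, 1.0))
        assert [v.cell_id for v in vectors] == ["a"]

    def test_empty_map_rejected(self):
        with pytest.raises(InvalidParameterError):
            translational_vectors(CellApicalMap("img", [], 1.0))

    def test_zero_displacement_all_degenerate(self):
        cell_map, _ = gen_apical_map(n_cells=9, displacement_frac=0.0, seed=0)
        assert all(v.degenerate for v in translational_vectors(cell_map))

    def test_huge_kappa_recovers_mu_exactly(self):
        cell_map, _ = gen_apical_map(n_cells=25, mu=0.0, kappa=1e6, seed=1)
        angles = np.array([v.angle_deg for v in translational_vectors(cell_map)])
        wrapped = np.minimum(angles, 360.0 - angles)
        assert np.all(wrapped < 0.5)


class TestSummary:
    def test_identical_angles_fully_within_bound(self):
        from ciliapol.translational import PolarityVector

        vectors = [PolarityVector(f"c{i}", 33.0, 1.0, False) for i in range(5)]
        s = summarize_translational(vectors, min_cells=1)
        assert s.fraction_within_bound == 1.0
        assert np.allclose(s.deviations.angles_deg, 0.0, atol=1e-9)

    def test_uniform_angles_approach_quarter(self, rng):
        from ciliapol.translational import PolarityVector

        angles = rng.uniform(0, 360, 20_000)
        vectors = [PolarityVector(str(i), a, 1.0, False) for i, a in enumerate(angles)]
        s = summarize_translational(vectors, reference="fixed_angle", fixed_angle_deg=0.0,
                                    min_cells=1)
        # uniform deviations: P(|d| <= 45) = 45/180 = 0.25
        assert s.fraction_within_bound == pytest.approx(0.25, abs=0.02)

    def test_all_degenerate_rejected(self):
        from ciliapol.translational import PolarityVector

        vectors = [PolarityVector("c", 0.0, 0.0, True)]
        with pytest.raises(InvalidParameterError):
            summarize_translational(vectors)

    def test_below_minimum_cells_warns(self):
        cell_map, _ = gen_apical_map(n_cells=20, seed=5)
        _, s = analyze_map(cell_map, min_cells=30)
        assert any("minimum" in w for w in s.warnings)

    def test_rotating_bb_leaves_fraction_unchanged(self):
        cell_map, _ = gen_apical_map(n_cells=40, kappa=2.0, seed=9)
        _, s0 = analyze_map(cell_map, min_cells=1)
        rotated_cells = []
        delta = math.radians(50.0)
        for c in cell_map.cells:
            cx, cy = polygon_centroid(c.polygon)
            dx, dy = c.bb_centroid[0] - cx, c.bb_centroid[1] - cy
            # rotate offsets about the cell centre by a common angle (image coords)
            rdx = dx * math.cos(delta) - dy * math.sin(delta)
            rdy = dx * math.sin(delta) + dy * math.cos(delta)
            rotated_cells.append(CellRecord(c.cell_id, c.polygon, (cx + rdx, cy + rdy)))
        _, s1 = analyze_map(
            CellApicalMap("rot", rotated_cells, cell_map.pixel_size), min_cells=1
        )
        assert s1.fraction_within_bound == pytest.approx(s0.fraction_within_bound)
        assert np.allclose(
            np.sort(s1.deviations.angles_deg), np.sort(s0.deviations.angles_deg), atol=1e-8
        )

    def test_fraction_monotone_in_concentration(self):
        """Mean polarised fraction grows with kappa over {0, 1, 2, 4, 8}."""
        means = []
        for kappa in (0.0, 1.0, 2.0, 4.0, 8.0):
            fracs = [
                analyze_map(
                    gen_apical_map(50, kappa=kappa, seed=int(1000 * kappa) + s)[0],
                    min_cells=1,
                )[1].fraction_within_bound
                for s in range(50)
            ]
            means.append(np.mean(fracs))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_area_statistics_reported(self):
        cell_map, _ = gen_apical_map(n_cells=36, mean_area=60.0, area_cv=0.15, seed=3)
        _, s = analyze_map(cell_map)
        assert s.mean_area_um2 == pytest.approx(60.0, rel=0.15)
        assert s.sem_area_um2 > 0.0
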