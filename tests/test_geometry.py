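"""Reference-shape geometry: vertices, edge angles, nearest edge, periphery crossing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point

from pistonalign._angles import axial_difference
from pistonalign.errors import InvalidOutlineError, UnsupportedShapeKindError
from pistonalign.geometry import ReferenceShape, ShapeKind
from pistonalign.morphometry import CellOutline

from conftest import make_ellipse_outline


class TestShapeConstruction:
    def test_size_must_be_positive(self):
        with pytest.raises(ValueError):
            ReferenceShape(ShapeKind.CIRCLE, (0, 0), 0.0)

    @pytest.mark.parametrize(
        "kind,k,expected",
        [(ShapeKind.TRIANGLE, 61.0, 1.0), (ShapeKind.SQUARE, 95.0, 5.0),
         (ShapeKind.SQUARE, -10.0, 80.0), (ShapeKind.CIRCLE, 33.0, 0.0)],
    )
    def test_rotation_k_normalized_to_symmetry_period(self, kind, k, expected):
        assert ReferenceShape(kind, (0, 0), 100.0, rotation_k=k).rotation_k == pytest.approx(expected)

    def test_square_vertices_on_circumscribed_circle(self):
        s = ReferenceShape(ShapeKind.SQUARE, (0, 0), 2 * np.sqrt(2))
        np.testing.assert_allclose(
            s.vertices(), [(1, 1), (-1, 1), (-1, -1), (1, -1)], atol=1e-12
        )

    def test_circle_has_no_vertices(self):
        assert ReferenceShape(ShapeKind.CIRCLE, (5, 5), 10.0).vertices().shape == (0, 2)

    def test_triangle_rotation_k_rotates_each_vertex(self):
        base = ReferenceShape(ShapeKind.TRIANGLE, (0, 0), 100.0)
        rot = ReferenceShape(ShapeKind.TRIANGLE, (0, 0), 100.0, rotation_k=15.0)
        angles0 = np.degrees(np.arctan2(base.vertices()[:, 1], base.vertices()[:, 0]))
        angles15 = np.degrees(np.arctan2(rot.vertices()[:, 1], rot.vertices()[:, 0]))
        np.testing.assert_allclose((angles15 - angles0) % 360, 15.0, atol=1e-9)

    def test_vertices_equidistant_from_centroid(self):
        s = ReferenceShape(ShapeKind.TRIANGLE, (3, -2), 250.0, rotation_k=17.0)
        d = np.hypot(*(s.vertices() - np.array([3, -2])).T)
        np.testing.assert_allclose(d, 125.0, atol=1e-12)


class TestEdgeAngles:
    def test_axis_aligned_square(self, square_shape):
        assert sorted(np.round(square_shape.edge_angles(), 9)) == [0, 0, 90, 90]

    def test_equilateral_triangle(self, triangle_shape):
        assert sorted(np.round(triangle_shape.edge_angles(), 9)) == [0, 60, 120]

    def test_rotation_adds_k(self):
        s = ReferenceShape(ShapeKind.SQUARE, (0, 0), 200.0, rotation_k=5.0)
        assert sorted(np.round(s.edge_angles(), 9)) == [5, 5, 95, 95]

    def test_circle_raises(self, circle_shape):
        with pytest.raises(UnsupportedShapeKindError):
            circle_shape.edge_angles()

    @pytest.mark.parametrize("kind,step", [(ShapeKind.TRIANGLE, 60.0), (ShapeKind.SQUARE, 90.0)])
    def test_edges_differ_by_symmetry_step(self, kind, step):
        s = ReferenceShape(kind, (1, 2), 140.0, rotation_k=23.0)
        ang = np.sort(s.edge_angles() % step)
        np.testing.assert_allclose(ang, ang[0], atol=1e-9)

    def test_invariant_under_vertex_reversal(self, triangle_shape):
        v = triangle_shape.vertices()[::-1]
        d = np.roll(v, -1, axis=0) - v
        reversed_angles = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 180.0
        reversed_angles[reversed_angles > 180 - 1e-9] = 0.0
        assert sorted(np.round(reversed_angles, 9)) == sorted(np.round(triangle_shape.edge_angles(), 9))


class TestNearestEdge:
    def test_square_sides(self):
        s = ReferenceShape(ShapeKind.SQUARE, (0, 0), 200.0 * np.sqrt(2))  # side 200
        assert s.nearest_edge_angle((0, 101)) == pytest.approx(0.0)
        assert s.nearest_edge_angle((101, 0)) == pytest.approx(90.0)

    def test_triangle_edge_just_outside(self, triangle_shape):
        # midpoint of the edge at direction 60 deg, pushed slightly outward
        v = triangle_shape.vertices()
        angles = triangle_shape.edge_angles()
        i = int(np.argmin(np.abs(angles - 60.0)))
        mid = (v[i] + v[(i + 1) % 3]) / 2
        outward = mid / np.linalg.norm(mid)
        assert triangle_shape.nearest_edge_angle(tuple(mid + 2 * outward)) == pytest.approx(60.0)

    def test_circle_raises(self, circle_shape):
        with pytest.raises(UnsupportedShapeKindError):
            circle_shape.nearest_edge_angle((1, 1))

    @given(
        theta=st.floats(0, 29.9), k=st.floats(0, 29.9),
        px=st.floats(-400, 400), py=st.floats(-400, 400),
        kind=st.sampled_from([ShapeKind.TRIANGLE, ShapeKind.SQUARE]),
    )
    @settings(max_examples=80, deadline=None)
    def test_corotation_shifts_angle_by_theta(self, theta, k, px, py, kind):
        """Rotating shape and query point together rotates the edge angle by theta.

        theta and k are kept inside the rotation_k normalization window, where
        adding theta to rotation_k is a faithful rotation of the vertex set.
        """
        from hypothesis import assume

        s = ReferenceShape(kind, (0, 0), 300.0, rotation_k=k)
        d2 = np.sort(s._edge_distances_sq((px, py)))
        assume(d2[1] - d2[0] > 1e-6)  # near-ties may legitimately flip edges
        s_rot = ReferenceShape(kind, (0, 0), 300.0, rotation_k=k + theta)
        t = np.radians(theta)
        p_rot = (px * np.cos(t) - py * np.sin(t), px * np.sin(t) + py * np.cos(t))
        a = s.nearest_edge_angle((px, py))
        b = s_rot.nearest_edge_angle(p_rot)
        assert axial_difference(a + theta, b) < 1e-9

    def test_boundary_distance_circle_and_polygon(self, circle_shape, square_shape):
        assert circle_shape.boundary_distance((160, 0)) == pytest.approx(10.0)
        assert circle_shape.boundary_distance((0, 0)) == pytest.approx(150.0)
        v = square_shape.vertices()
        mid = (v[0] + v[1]) / 2
        assert square_shape.boundary_distance(tuple(mid)) == pytest.approx(0.0, abs=1e-9)


class TestPeripheryCrossing:
    def test_cell_on_circle_boundary_crosses(self, circle_shape):
        cell = make_ellipse_outline(center=(150.0, 0.0), semi_major=12, semi_minor=5)
        assert circle_shape.crosses_periphery(cell)

    def test_cell_fully_inside_does_not_cross(self, circle_shape):
        cell = make_ellipse_outline(center=(0.0, 0.0), semi_major=12, semi_minor=5)
        assert not circle_shape.crosses_periphery(cell)

    def test_cell_fully_outside_does_not_cross(self, circle_shape):
        cell = make_ellipse_outline(center=(400.0, 0.0), semi_major=12, semi_minor=5)
        assert not circle_shape.crosses_periphery(cell)

    def test_polygon_shape_crossing(self, triangle_shape):
        v = triangle_shape.vertices()
        mid = (v[0] + v[1]) / 2
        assert triangle_shape.crosses_periphery(make_ellipse_outline(center=tuple(mid)))
        assert not triangle_shape.crosses_periphery(make_ellipse_outline(center=(0, 0)))

    def test_zero_area_outline_raises(self, circle_shape, triangle_shape):
        flat = CellOutline("flat", [(0, 0), (1, 0), (2, 0)])
        with pytest.raises(InvalidOutlineError):
            circle_shape.crosses_periphery(flat)
        with pytest.raises(InvalidOutlineError):
            triangle_shape.crosses_periphery(flat)

    @given(
        dx=st.floats(-500, 500), dy=st.floats(-500, 500),
        cx=st.floats(-200, 200), cy=st.floats(-200, 200),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, dx, dy, cx, cy):
        shape = ReferenceShape(ShapeKind.CIRCLE, (0.0, 0.0), 300.0)
        cell = make_ellipse_outline(center=(cx, cy))
        shape_t = shape.translated((dx, dy))
        cell_t = CellOutline("t", cell.vertex_array + np.array([dx, dy]))
        assert shape.crosses_periphery(cell) == shape_t.crosses_periphery(cell_t)

    def test_circle_decision_matches_buffered_curve_oracle(self, rng, circle_shape):
        """Independent oracle: shapely intersection with a densely buffered circle."""
        ring = Point(circle_shape.centroid).buffer(circle_shape.radius, quad_segs=512).exterior
        for _ in range(80):
            center = rng.uniform(-320, 320, size=2)
            cell = make_ellipse_outline(center=tuple(center),
                                        semi_major=rng.uniform(5, 40),
                                        semi_minor=rng.uniform(3, 5))
            if abs(circle_shape.boundary_distance(tuple(center)) - 40) < 1.0:
                continue  # skip knife-edge cases where the polygonized oracle may differ
            assert circle_shape.crosses_periphery(cell) == cell.polygon.intersects(ring)

    def test_cell_engulfing_whole_circle_crosses(self):
        tiny = ReferenceShape(ShapeKind.CIRCLE, (0, 0), 4.0)
        big_cell = make_ellipse_outline(center=(0, 0), semi_major=50, semi_minor=30)
        assert tiny.crosses_periphery(big_cell)
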