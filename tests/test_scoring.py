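"""Shape-relative angle computation, binning, region scoring and control overlay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point

from pistonalign._angles import axial_difference
from pistonalign.errors import CellAtCentroidError, PlacementInfeasibleError
from pistonalign.geometry import ReferenceShape, ShapeKind
from pistonalign.morphometry import CellOutline
from pistonalign.scoring import (
    AngleBin,
    UNIFORM_BIN_FRACTIONS,
    angle_relative_to_edge,
    angle_relative_to_tangent,
    beta_angle,
    bin_angle,
    control_overlay,
    score_region,
)

from conftest import make_ellipse_outline


class TestBetaAngle:
    @pytest.mark.parametrize("xy,expected", [((1, 0), 0), ((0, 1), 90), ((-1, 1), 135),
                                             ((0, -2), 270)])
    def test_quadrant_aware(self, xy, expected):
        assert beta_angle(*xy) == pytest.approx(expected)

    def test_zero_vector_raises(self):
        with pytest.raises(CellAtCentroidError):
            beta_angle(0.0, 0.0)


class TestRelativeAngles:
    @pytest.mark.parametrize("alpha,beta,expected", [(30, 30, 90), (120, 30, 0), (10, 50, 50)])
    def test_tangent_relative(self, alpha, beta, expected):
        assert angle_relative_to_tangent(alpha, beta) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha,edge,expected", [(60, 60, 0), (150, 60, 90), (5, 175, 10)])
    def test_edge_relative(self, alpha, edge, expected):
        assert angle_relative_to_edge(alpha, edge) == pytest.approx(expected)

    @given(alpha=st.floats(0, 180, exclude_max=True), beta=st.floats(0, 360, exclude_max=True))
    @settings(max_examples=200, deadline=None)
    def test_tangent_equals_edge_formulation_with_analytic_tangent(self, alpha, beta):
        """Circle scoring agrees with edge-relative scoring against the tangent
        direction at the ray-periphery intersection (perpendicular to the radius)."""
        tangent_dir = (beta + 90.0) % 180.0
        a = angle_relative_to_tangent(alpha, beta)
        b = angle_relative_to_edge(alpha, tangent_dir)
        assert axial_difference(a, b) <= 1e-9


class TestBinning:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (90, AngleBin.RADIAL), (70, AngleBin.RADIAL), (110, AngleBin.RADIAL),
            (15, AngleBin.PERIPHERAL), (0, AngleBin.PERIPHERAL), (179.9, AngleBin.PERIPHERAL),
            (160.5, AngleBin.PERIPHERAL),
            (50, AngleBin.OBLIQUE_NEAR), (69.9, AngleBin.OBLIQUE_NEAR),
            (110.1, AngleBin.OBLIQUE_NEAR), (130, AngleBin.OBLIQUE_NEAR),
            (20, AngleBin.OBLIQUE_FAR), (49.9, AngleBin.OBLIQUE_FAR),
            (140, AngleBin.OBLIQUE_FAR), (160, AngleBin.OBLIQUE_FAR),
        ],
    )
    def test_bin_assignment(self, angle, expected):
        assert bin_angle(angle) is expected

    @pytest.mark.parametrize("bad", [-0.001, 180.0, 200.0])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValueError):
            bin_angle(bad)

    def test_partition_widths(self, rng):
        """Every angle gets exactly one bin; empirical fractions match 40/40/40/60 over 180."""
        angles = rng.uniform(0, 180, 50_000)
        bins = np.array([bin_angle(a).value for a in angles])
        for b, frac in UNIFORM_BIN_FRACTIONS.items():
            se = np.sqrt(frac * (1 - frac) / angles.size)
            assert abs((bins == b.value).mean() - frac) < 4 * se


class TestScoreRegion:
    def test_radial_cell_on_circle(self, circle_shape):
        # cell at (r, 0) elongated along x: alpha = 0, beta = 0 -> relative 90, RADIAL
        cell = make_ellipse_outline(center=(150.0, 0.0), semi_major=12, semi_minor=4,
                                    angle_deg=0.0)
        result = score_region(circle_shape, [cell])
        assert len(result.records) == 1
        rec = result.records[0]
        assert rec.relative_angle == pytest.approx(90.0, abs=0.2)
        assert rec.bin is AngleBin.RADIAL
        assert rec.beta_or_edge == pytest.approx(0.0, abs=0.1)

    def test_all_alpha_equals_beta_is_all_radial(self, circle_shape, rng):
        cells = []
        for i, theta in enumerate(rng.uniform(0, 360, 25)):
            c = 150.0 * np.array([np.cos(np.radians(theta)), np.sin(np.radians(theta))])
            cells.append(make_ellipse_outline(center=tuple(c), semi_major=12, semi_minor=4,
                                              angle_deg=theta % 180, cell_id=f"c{i}"))
        result = score_region(circle_shape, cells)
        assert len(result.records) == 25
        assert all(r.bin is AngleBin.RADIAL for r in result.records)

    def test_no_crossing_cells_yields_empty(self, circle_shape):
        cells = [make_ellipse_outline(center=(0, 0)), make_ellipse_outline(center=(400, 400))]
        result = score_region(circle_shape, cells)
        assert result.records == []
        assert result.excluded["not_crossing"] == 2

    def test_isotropic_cells_excluded_and_tallied(self, circle_shape):
        t = 2 * np.pi * np.arange(6) / 6
        hexagon = CellOutline("hex", np.column_stack([150 + 8 * np.cos(t), 8 * np.sin(t)]))
        result = score_region(circle_shape, [hexagon])
        assert result.records == []
        assert result.excluded["no_orientation"] == 1

    def test_min_aspect_filter(self, circle_shape):
        fat = make_ellipse_outline(center=(150, 0), semi_major=8, semi_minor=7.5)
        result = score_region(circle_shape, [fat], min_aspect=1.5)
        assert result.excluded["below_min_aspect"] == 1

    def test_polygon_edge_relative_scoring(self, square_shape):
        v = square_shape.vertices()
        mid = (v[0] + v[1]) / 2  # top edge, direction 0
        cell = make_ellipse_outline(center=tuple(mid), semi_major=12, semi_minor=4,
                                    angle_deg=90.0)
        rec = score_region(square_shape, [cell]).records[0]
        assert rec.beta_or_edge == pytest.approx(0.0)
        assert rec.relative_angle == pytest.approx(90.0, abs=0.2)
        assert rec.bin is AngleBin.RADIAL

    @pytest.mark.parametrize("kind", [ShapeKind.CIRCLE, ShapeKind.TRIANGLE, ShapeKind.SQUARE])
    def test_scene_rotation_invariance(self, kind, rng):
        """Rotating shape and all outlines together leaves relative angles unchanged."""
        k0 = 10.0
        shape = ReferenceShape(kind, (0.0, 0.0), 300.0, rotation_k=k0)
        alphas = rng.uniform(0, 180, 20)
        if kind is ShapeKind.CIRCLE:
            thetas = rng.uniform(0, 360, 20)
            centers = [(150 * np.cos(np.radians(t)), 150 * np.sin(np.radians(t)))
                       for t in thetas]
        else:
            ring = shape.footprint().exterior
            centers = [tuple(np.asarray(ring.interpolate(f, normalized=True).coords[0]))
                       for f in rng.uniform(0, 1, 20)]
        cells = [
            make_ellipse_outline(center=c, semi_major=12, semi_minor=4,
                                 angle_deg=a, cell_id=f"c{i}")
            for i, (c, a) in enumerate(zip(centers, alphas))
        ]
        base = {r.cell_id: r.relative_angle for r in score_region(shape, cells).records}
        assert len(base) == 20
        theta = 24.0  # keeps rotation_k inside its normalization window
        rotm = np.array([[np.cos(np.radians(theta)), -np.sin(np.radians(theta))],
                         [np.sin(np.radians(theta)), np.cos(np.radians(theta))]])
        shape_rot = ReferenceShape(kind, (0.0, 0.0), 300.0, rotation_k=k0 + theta)
        cells_rot = [CellOutline(c.cell_id, c.vertex_array @ rotm.T) for c in cells]
        rotated = {r.cell_id: r.relative_angle for r in score_region(shape_rot, cells_rot).records}
        assert set(rotated) == set(base)
        for cid in base:
            assert axial_difference(base[cid], rotated[cid]) <= 0.1


class TestControlOverlay:
    def test_deterministic_given_seed(self, circle_shape):
        fov = (0, 0, 1000, 600)
        a = control_overlay(circle_shape, fov, circle_shape.footprint(), rng_seed=42)
        b = control_overlay(circle_shape, fov, circle_shape.footprint(), rng_seed=42)
        assert a.centroid == b.centroid

    def test_infeasible_when_exclusion_covers_fov(self, circle_shape):
        from shapely.geometry import box

        fov = (0, 0, 400, 400)
        with pytest.raises(PlacementInfeasibleError):
            control_overlay(circle_shape, fov, box(-200, -200, 600, 600), rng_seed=1,
                            max_tries=200)

    def test_placements_never_overlap_exclusion(self, circle_shape, rng):
        exclusion = Point(200.0, 200.0).buffer(150.0)
        fov = (0, 0, 1200, 800)
        for _ in range(10_000):
            placed = control_overlay(circle_shape, fov, exclusion, rng_seed=rng)
            cx, cy = placed.centroid
            assert exclusion.distance(Point(cx, cy)) >= placed.radius - 1e-9
            assert 150 <= cx <= 1050 and 150 <= cy <= 650

    def test_triangle_footprint_stays_in_fov(self, triangle_shape):
        fov = (0, 0, 800, 800)
        placed = control_overlay(triangle_shape, fov, None, rng_seed=7)
        xmin, ymin, xmax, ymax = placed.footprint().bounds
        assert xmin >= 0 and ymin >= 0 and xmax <= 800 and ymax <= 800
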