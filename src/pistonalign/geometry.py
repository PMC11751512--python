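"""Reference-shape geometry for micro-piston footprints.

A micro-piston is a PDMS structure suspended above a cell monolayer; its projected
footprint (circle, equilateral triangle, or square) is the reference against which
cell elongation angles are scored.  Shapes are parameterized by the diameter of
their circumscribed circle, so a "300 um" circle, triangle and square share one
scale number, and by a correction angle ``rotation_k`` describing how far the
fabricated polygon's edges deviate from the canonical axis-aligned orientation.

Canonical orientation (``rotation_k = 0``): one edge of the square and one edge of
the triangle are parallel to the x-axis of the field of view.  All coordinates use
a mathematical y-up frame; importers of image-native (y-down) data flip on read.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from shapely.geometry import Point, Polygon

from ._angles import fold180
from .errors import UnsupportedShapeKindError

if TYPE_CHECKING:  # pragma: no cover
    from .morphometry import CellOutline

__all__ = [
    "ShapeKind",
    "ReferenceShape",
    "shape_vertices",
    "edge_angles",
    "nearest_edge_angle",
    "outline_crosses_periphery",
]


class ShapeKind(str, enum.Enum):
    CIRCLE = "circle"
    TRIANGLE = "triangle"
    SQUARE = "square"


# First-vertex polar angle at rotation_k = 0, chosen so one edge is x-parallel.
_CANONICAL_START = {ShapeKind.TRIANGLE: 90.0, ShapeKind.SQUARE: 45.0}
_N_VERTICES = {ShapeKind.TRIANGLE: 3, ShapeKind.SQUARE: 4}
# Edge directions repeat with this period, so rotation_k is only meaningful modulo it.
_K_PERIOD = {ShapeKind.TRIANGLE: 60.0, ShapeKind.SQUARE: 90.0}


@dataclass(frozen=True)
class ReferenceShape:
    """Footprint of one micro-piston.

    Parameters
    ----------
    kind
        ``circle``, ``triangle`` or ``square``.
    centroid
        (x, y) of the footprint centroid, in the dataset's length unit.
    size
        Diameter of the circle, or of the circumscribed circle for polygons.
    rotation_k
        Correction angle in degrees by which the fabricated polygon's edges
        deviate from the canonical orientation; normalized to [0, 60) for the
        triangle and [0, 90) for the square, ignored for the circle.
    """

    kind: ShapeKind
    centroid: tuple[float, float]
    size: float
    rotation_k: float = 0.0
    units: str = "um"

    def __post_init__(self) -> None:
        kind = ShapeKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "centroid", (float(self.centroid[0]), float(self.centroid[1])))
        if not (self.size > 0):
            raise ValueError(f"shape size must be > 0, got {self.size}")
        k = 0.0 if kind is ShapeKind.CIRCLE else float(self.rotation_k) % _K_PERIOD[kind]
        object.__setattr__(self, "rotation_k", k)

    # -- basic descriptors -------------------------------------------------

    @property
    def radius(self) -> float:
        """Circumscribed-circle radius (size / 2)."""
        return self.size / 2.0

    @property
    def is_polygon(self) -> bool:
        return self.kind is not ShapeKind.CIRCLE

    def vertices(self) -> np.ndarray:
        """Polygon vertices in CCW order, shape (n, 2); empty (0, 2) for a circle."""
        if self.kind is ShapeKind.CIRCLE:
            return np.empty((0, 2), dtype=float)
        n = _N_VERTICES[self.kind]
        start = math.radians(_CANONICAL_START[self.kind] + self.rotation_k)
        angles = start + 2.0 * np.pi * np.arange(n) / n
        cx, cy = self.centroid
        return np.column_stack(
            [cx + self.radius * np.cos(angles), cy + self.radius * np.sin(angles)]
        )

    def edge_angles(self) -> np.ndarray:
        """Direction of each edge vs the x-axis, degrees in [0, 180); polygon only."""
        if not self.is_polygon:
            raise UnsupportedShapeKindError("edge angles are undefined for a circle")
        v = self.vertices()
        d = np.roll(v, -1, axis=0) - v
        ang = fold180(np.degrees(np.arctan2(d[:, 1], d[:, 0])))
        ang[ang > 180.0 - 1e-9] = 0.0  # fold noise: a hair below 0 deg is the 0 axis
        return ang

    def footprint(self, circle_quad_segs: int = 64) -> Polygon:
        """Filled footprint as a shapely polygon (a circle is approximated)."""
        if self.kind is ShapeKind.CIRCLE:
            return Point(self.centroid).buffer(self.radius, quad_segs=circle_quad_segs)
        return Polygon(self.vertices())

    def translated(self, new_centroid: tuple[float, float]) -> "ReferenceShape":
        return ReferenceShape(self.kind, tuple(new_centroid), self.size, self.rotation_k, self.units)

    # -- queries -----------------------------------------------------------

    def _edge_distances_sq(self, point: tuple[float, float]) -> np.ndarray:
        """Squared point-to-segment distance to each polygon edge."""
        v = self.vertices()
        p = np.asarray(point, dtype=float)
        a = v
        b = np.roll(v, -1, axis=0)
        ab = b - a
        t = np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab)
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[:, None] * ab
        return np.einsum("ij,ij->i", p - proj, p - proj)

    def nearest_edge_index(self, point: tuple[float, float]) -> int:
        """Index of the edge segment nearest to ``point`` (ties -> lowest index)."""
        if not self.is_polygon:
            raise UnsupportedShapeKindError("a circle has no edges")
        return int(np.argmin(self._edge_distances_sq(point)))  # argmin keeps lowest index on ties

    def boundary_distance(self, point: tuple[float, float]) -> float:
        """Euclidean distance from ``point`` to the periphery curve."""
        if self.kind is ShapeKind.CIRCLE:
            dx = point[0] - self.centroid[0]
            dy = point[1] - self.centroid[1]
            return abs(math.hypot(dx, dy) - self.radius)
        return float(np.sqrt(self._edge_distances_sq(point).min()))

    def nearest_edge_angle(self, point: tuple[float, float]) -> float:
        """Edge angle (degrees in [0,180)) of the edge nearest to ``point``."""
        return float(self.edge_angles()[self.nearest_edge_index(point)])

    def crosses_periphery(self, outline: "CellOutline") -> bool:
        """True iff the cell outline intersects this shape's periphery curve.

        A cell "crosses" when its filled polygon contains points on the boundary —
        i.e. it straddles or touches the projected piston outline.  For the circle
        this is decided exactly from distances (no polygonal approximation of the
        circle): vertices on both sides of the radius imply a crossing, all
        vertices inside imply containment in the disk, and when every vertex is
        outside the decision falls to the centre-to-polygon distance.
        """
        verts = outline.vertex_array
        if self.kind is ShapeKind.CIRCLE:
            _require_nonzero_area(outline)
            c = np.asarray(self.centroid)
            d = np.sqrt(((verts - c) ** 2).sum(axis=1))
            r = self.radius
            if d.max() < r:          # polygon (subset of its hull) fully inside the disk
                return False
            if d.min() <= r:         # vertices straddle or touch the periphery
                return True
            # all vertices strictly outside: either an edge dips into the disk,
            # or the polygon wraps around the whole disk, or they are disjoint
            if _min_point_to_edges(c, verts) <= r:
                return True
            return _point_in_polygon(c, verts)
        ring = Polygon(self.vertices()).exterior
        return bool(outline.polygon.intersects(ring))


def _require_nonzero_area(outline: "CellOutline") -> None:
    v = outline.vertex_array
    x, y = v[:, 0], v[:, 1]
    area2 = np.abs((x * np.roll(y, -1) - np.roll(x, -1) * y).sum())
    if area2 == 0.0:
        from .errors import InvalidOutlineError

        raise InvalidOutlineError(f"outline {outline.cell_id!r} has zero area")


def _min_point_to_edges(p: np.ndarray, verts: np.ndarray) -> float:
    a = verts
    b = np.roll(verts, -1, axis=0)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.sqrt(np.einsum("ij,ij->i", p - proj, p - proj).min()))


def _point_in_polygon(p: np.ndarray, verts: np.ndarray) -> bool:
    """Even-odd ray cast; boundary cases are irrelevant to callers here."""
    x, y = p
    vx, vy = verts[:, 0], verts[:, 1]
    vx1, vy1 = np.roll(vx, -1), np.roll(vy, -1)
    straddles = (vy > y) != (vy1 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xints = vx + (y - vy) * (vx1 - vx) / (vy1 - vy)
    return bool(np.count_nonzero(straddles & (x < xints)) % 2)


# ---------------------------------------------------------------------------
# Functional surface (thin wrappers over the dataclass methods)
# ---------------------------------------------------------------------------

def shape_vertices(shape: ReferenceShape) -> np.ndarray:
    return shape.vertices()


def edge_angles(shape: ReferenceShape) -> np.ndarray:
    return shape.edge_angles()


def nearest_edge_angle(shape: ReferenceShape, point: tuple[float, float]) -> float:
    return shape.nearest_edge_angle(point)


def outline_crosses_periphery(shape: ReferenceShape, outline: "CellOutline") -> bool:
    return shape.crosses_periphery(outline)
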