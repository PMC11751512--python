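"""Label-free cell morphometry from polygonal outlines.

The cell axis is the major axis of the ellipse matching the outline's second-order
area moments — the same quantity ImageJ's "fit ellipse" converges to as pixel size
shrinks, but computed here in closed form from the polygon's contour integrals
(Green's theorem), so results are exact and resolution-free.

The orientation ``alpha`` is reported from the field-of-view x-axis on the axial
scale [0, 180).  Outlines whose moment tensor is isotropic within tolerance (e.g.
regular polygons, near-circular cells) have no defined major axis and are flagged
``orientation_defined = False`` so downstream scoring can exclude and tally them.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Optional

import numpy as np
from shapely.geometry import Polygon

from ._angles import fold180
from .errors import InvalidOutlineError

__all__ = [
    "CellOutline",
    "CellMorphometry",
    "polygon_centroid",
    "polygon_moments",
    "fit_ellipse_orientation",
    "ISOTROPY_RTOL",
]

# orientation_defined = False when (mu20-mu02)^2 + 4 mu11^2 < ISOTROPY_RTOL * (mu20+mu02)^2
ISOTROPY_RTOL = 1e-12


@dataclass(frozen=True, eq=False)
class CellOutline:
    """Closed polygon outlining one cell body.

    Vertices are stored open (last != first; closure is implied), in the same
    length unit as the reference shapes of the dataset.  ``day`` is the culture
    day label and ``region`` is ``"piston"`` (under the projected periphery) or
    ``"control"`` (random area of the monolayer).
    """

    cell_id: str
    vertices: object  # (n, 2) array-like of (x, y)
    day: int = 0
    region: str = "piston"

    @cached_property
    def vertex_array(self) -> np.ndarray:
        arr = np.asarray(self.vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
            raise InvalidOutlineError(
                f"outline {self.cell_id!r} needs >= 3 (x, y) vertices, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidOutlineError(f"outline {self.cell_id!r} has non-finite coordinates")
        return arr

    @cached_property
    def polygon(self) -> Polygon:
        poly = Polygon(self.vertex_array)
        if poly.area == 0:
            raise InvalidOutlineError(f"outline {self.cell_id!r} has zero area")
        return poly

    def validate(self) -> "CellOutline":
        """Full validity check (simplicity + nonzero area); returns self."""
        if not self.polygon.is_valid:
            raise InvalidOutlineError(f"outline {self.cell_id!r} is self-intersecting")
        return self


@dataclass(frozen=True)
class CellMorphometry:
    """Centroid and moment-ellipse descriptors of one outline.

    ``major_len``/``minor_len`` are full axis lengths of the ellipse that has the
    polygon's area and the moment tensor's axis ratio; ``alpha`` is the major-axis
    orientation in [0, 180), present only when ``orientation_defined``.
    """

    cell_id: str
    centroid: tuple[float, float]
    alpha: Optional[float]
    major_len: float
    minor_len: float
    orientation_defined: bool
    day: int = 0
    region: str = "piston"

    @property
    def aspect(self) -> float:
        return self.major_len / self.minor_len


def polygon_moments(vertices: np.ndarray):
    """Area, centroid and central second moments of a simple polygon.

    Returns ``(area, (cx, cy), mu20, mu11, mu02)`` where the mu's are per-unit-area
    central moments (the covariance of the uniform density over the filled polygon).
    Closed-form shoelace/Green's-theorem sums; independent of vertex orientation.
    """
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a_signed = 0.5 * cross.sum()
    if a_signed == 0.0:
        raise InvalidOutlineError("zero-area polygon")
    cx = ((x + x1) * cross).sum() / (6.0 * a_signed)
    cy = ((y + y1) * cross).sum() / (6.0 * a_signed)
    # raw second moments over the filled polygon, about the origin
    sxx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    syy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    sxy = ((x * y1 + 2.0 * x * y + 2.0 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    mu20 = sxx / a_signed - cx * cx
    mu02 = syy / a_signed - cy * cy
    mu11 = sxy / a_signed - cx * cy
    return abs(a_signed), (cx, cy), mu20, mu11, mu02


def polygon_centroid(outline: CellOutline) -> tuple[float, float]:
    """Area-weighted centroid of the outline polygon."""
    _, c, *_ = polygon_moments(outline.vertex_array)
    return c


def fit_ellipse_orientation(outline: CellOutline) -> CellMorphometry:
    """Fit the moment-matched ellipse and return the cell's morphometry.

    The axis ratio comes from the eigenvalues of the central moment tensor and the
    axis lengths are scaled so the ellipse area equals the polygon area.  The
    orientation is ``alpha = 1/2 * atan2(2 mu11, mu20 - mu02)`` folded to [0, 180).
    """
    area, centroid, mu20, mu11, mu02 = polygon_moments(outline.vertex_array)
    trace = mu20 + mu02
    aniso2 = (mu20 - mu02) ** 2 + 4.0 * mu11 ** 2
    defined = aniso2 >= ISOTROPY_RTOL * trace ** 2

    # eigenvalues of [[mu20, mu11], [mu11, mu02]]
    half_span = 0.5 * np.sqrt(aniso2)
    lam1 = 0.5 * trace + half_span
    lam2 = 0.5 * trace - half_span
    if lam2 <= 0:
        # numerically collapsed (sliver) polygons; treat as maximally elongated
        lam2 = np.finfo(float).tiny
    ratio = np.sqrt(lam1 / lam2)  # major/minor
    semi_major = np.sqrt(area * ratio / np.pi)
    semi_minor = area / (np.pi * semi_major)

    alpha = None
    if defined:
        alpha = float(fold180(np.degrees(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02))))
    return CellMorphometry(
        cell_id=outline.cell_id,
        centroid=centroid,
        alpha=alpha,
        major_len=2.0 * semi_major,
        minor_len=2.0 * semi_minor,
        orientation_defined=bool(defined),
        day=outline.day,
        region=outline.region,
    )
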