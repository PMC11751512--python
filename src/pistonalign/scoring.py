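"""Shape-relative elongation angles and the four-class angle binning.

For a cell whose outline crosses the projected periphery of a micro-piston, the
elongation angle is re-expressed relative to the local periphery direction:

* circle — via the position angle ``beta`` of the cell centroid seen from the
  piston centroid, ``relative = 90 - (beta - alpha)`` folded to [0, 180), so that
  90 means the cell axis points along the radius and 0/180 along the tangent;
* triangle / square — as the axial difference between ``alpha`` and the direction
  of the nearest polygon edge, with 90 perpendicular to (i.e. across) the edge.

Relative angles are grouped into four bins: radial (70-110), peripheral (<20 or
>160), and two oblique classes (50-70 / 110-130 and 20-50 / 130-160).  Boundary
conventions follow a half-open partition of [0, 180) and are a measure-zero
choice for continuous data.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from ._angles import fold180
from .errors import CellAtCentroidError, PlacementInfeasibleError
from .geometry import ReferenceShape, ShapeKind
from .morphometry import CellOutline, fit_ellipse_orientation

__all__ = [
    "AngleBin",
    "AlignmentRecord",
    "ScoreResult",
    "beta_angle",
    "angle_relative_to_tangent",
    "angle_relative_to_edge",
    "bin_angle",
    "score_region",
    "control_overlay",
    "UNIFORM_BIN_FRACTIONS",
]


class AngleBin(str, enum.Enum):
    """Four-class partition of the shape-relative angle scale [0, 180)."""

    RADIAL = "radial"              # [70, 110] — across the periphery
    PERIPHERAL = "peripheral"      # [0, 20) and (160, 180) — along the periphery
    OBLIQUE_NEAR = "oblique_near"  # [50, 70) and (110, 130]
    OBLIQUE_FAR = "oblique_far"    # [20, 50) and (130, 160]


BIN_ORDER = (AngleBin.RADIAL, AngleBin.PERIPHERAL, AngleBin.OBLIQUE_NEAR, AngleBin.OBLIQUE_FAR)

#: Expected bin fractions for uniformly random orientations (bin width / 180).
UNIFORM_BIN_FRACTIONS = {
    AngleBin.RADIAL: 40.0 / 180.0,
    AngleBin.PERIPHERAL: 40.0 / 180.0,
    AngleBin.OBLIQUE_NEAR: 40.0 / 180.0,
    AngleBin.OBLIQUE_FAR: 60.0 / 180.0,
}


def beta_angle(x_cell: float, y_cell: float) -> float:
    """Quadrant-aware position angle of the cell centroid relative to the piston
    centroid, degrees in [0, 360)."""
    if x_cell == 0.0 and y_cell == 0.0:
        raise CellAtCentroidError("cell centroid coincides with the shape centroid")
    return math.degrees(math.atan2(y_cell, x_cell)) % 360.0


def angle_relative_to_tangent(alpha: float, beta: float) -> float:
    """Cell angle relative to the tangent of a circular periphery: 90 - (beta - alpha),
    folded to [0, 180).  90 = radial, 0 = tangential."""
    return float(fold180(90.0 - (beta - alpha)))


def angle_relative_to_edge(alpha: float, edge_angle: float) -> float:
    """Axial difference between the cell axis and a polygon edge direction, folded
    to [0, 180) with the convention that 90 means perpendicular to the edge."""
    return float(fold180(alpha - edge_angle))


def bin_angle(relative_angle: float) -> AngleBin:
    """Assign a shape-relative angle in [0, 180) to its angle class."""
    a = float(relative_angle)
    if not (0.0 <= a < 180.0):
        raise ValueError(f"relative angle must be in [0, 180), got {a}")
    if 70.0 <= a <= 110.0:
        return AngleBin.RADIAL
    if a < 20.0 or a > 160.0:
        return AngleBin.PERIPHERAL
    if 50.0 <= a < 70.0 or 110.0 < a <= 130.0:
        return AngleBin.OBLIQUE_NEAR
    return AngleBin.OBLIQUE_FAR


@dataclass(frozen=True)
class AlignmentRecord:
    """One periphery-crossing cell's shape-relative elongation measurement."""

    cell_id: str
    day: int
    region: str
    x_cell: float           # centroid relative to the shape centroid
    y_cell: float
    alpha: float            # FoV-frame orientation, [0, 180)
    beta_or_edge: float     # beta for circle, nearest edge angle for polygons
    relative_angle: float   # [0, 180)
    bin: AngleBin


@dataclass
class ScoreResult:
    """Records for scored cells plus a tally of exclusions by reason."""

    records: list
    excluded: Counter

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "cell_id", "day", "region", "x_cell", "y_cell",
            "alpha", "beta_or_edge", "relative_angle", "bin",
        ]
        rows = [
            {c: (getattr(r, c).value if c == "bin" else getattr(r, c)) for c in cols}
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=cols)


def _score_one(shape: ReferenceShape, centroid, alpha: float):
    cx, cy = shape.centroid
    x_rel, y_rel = centroid[0] - cx, centroid[1] - cy
    if shape.kind is ShapeKind.CIRCLE:
        ref = beta_angle(x_rel, y_rel)
        rel = angle_relative_to_tangent(alpha, ref)
    else:
        ref = shape.nearest_edge_angle(centroid)
        rel = angle_relative_to_edge(alpha, ref)
    return x_rel, y_rel, ref, rel


def score_region(
    shape: ReferenceShape,
    outlines: Iterable[CellOutline],
    min_aspect: Optional[float] = None,
) -> ScoreResult:
    """Score every outline that crosses the shape's periphery.

    Cells are selected exactly as in the imaging procedure: only outlines that
    elongate across the projected periphery are measured.  Cells with an
    undefined orientation (isotropic moment tensor) — and, when ``min_aspect``
    is set, cells below that elongation — are excluded and tallied.
    """
    records: list[AlignmentRecord] = []
    excluded: Counter = Counter()
    for outline in outlines:
        if not shape.crosses_periphery(outline):
            excluded["not_crossing"] += 1
            continue
        morph = fit_ellipse_orientation(outline)
        if not morph.orientation_defined:
            excluded["no_orientation"] += 1
            continue
        if min_aspect is not None and morph.aspect < min_aspect:
            excluded["below_min_aspect"] += 1
            continue
        x_rel, y_rel, ref, rel = _score_one(shape, morph.centroid, morph.alpha)
        records.append(
            AlignmentRecord(
                cell_id=outline.cell_id,
                day=outline.day,
                region=outline.region,
                x_cell=x_rel,
                y_cell=y_rel,
                alpha=morph.alpha,
                beta_or_edge=ref,
                relative_angle=rel,
                bin=bin_angle(rel),
            )
        )
    return ScoreResult(records=records, excluded=excluded)


def control_overlay(
    shape: ReferenceShape,
    fov_bounds: Sequence[float],
    exclusion: Union[BaseGeometry, ReferenceShape, None],
    rng_seed: Union[int, np.random.Generator],
    max_tries: int = 10_000,
) -> ReferenceShape:
    """Place a copy of ``shape`` at a random piston-free position in the FoV.

    Mirrors the control procedure of overlaying the same piston geometry onto a
    randomly chosen area of the monolayer away from the piston.  ``fov_bounds``
    is (xmin, ymin, xmax, ymax); ``exclusion`` is the true piston region (a
    shapely geometry or another ReferenceShape) the control footprint must not
    overlap.  Placement is uniform rejection sampling, deterministic given the
    seed; infeasibility after ``max_tries`` draws raises.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    xmin, ymin, xmax, ymax = map(float, fov_bounds)
    if isinstance(exclusion, ReferenceShape):
        exclusion = exclusion.footprint()
    r = shape.radius
    lo_x, hi_x = xmin + r, xmax - r
    lo_y, hi_y = ymin + r, ymax - r
    if lo_x > hi_x or lo_y > hi_y:
        raise PlacementInfeasibleError("FoV is smaller than the shape footprint")
    for _ in range(max_tries):
        c = (rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y))
        candidate = shape.translated(c)
        if exclusion is None:
            return candidate
        if shape.kind is ShapeKind.CIRCLE:
            overlaps = exclusion.distance(Point(c)) < r
        else:
            overlaps = candidate.footprint().intersects(exclusion)
        if not overlaps:
            return candidate
    raise PlacementInfeasibleError(
        f"no non-overlapping placement found in {max_tries} draws"
    )
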