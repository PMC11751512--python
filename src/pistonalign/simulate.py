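"""Synthetic cell-monolayer generator with known ground truth.

No raw microscopy accompanies the analysis this package implements, so every
pipeline stage is exercised against simulated monolayers that carry the same
statistical structure the method assumes:

* elliptical cells polygonized with radial vertex jitter, placed by sequential
  rejection sampling with a minimum centre spacing (a cheap stand-in for
  monolayer packing);
* orientations that, within a zone around the projected piston periphery, are a
  mixture of a shape-aligned component — axial von Mises centred on the radial
  direction (90 deg on the shape-relative scale) — and a uniform component;
  outside the zone, and everywhere in control regions, orientations are uniform;
* day-dependent cell-count growth reaching a 1.8-fold increase at Day 2.

Every draw is governed by one seed, and the ground-truth table records each
cell's true orientation, zone membership and latent aligned/uniform label, so
parameter-recovery and power experiments can compare the pipeline's output with
what was actually simulated.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from ._angles import fold180
from .errors import PlacementInfeasibleError
from .geometry import ReferenceShape, ShapeKind
from .morphometry import CellOutline
from .scoring import beta_angle

__all__ = [
    "SyntheticConfig",
    "sample_orientation",
    "generate_cell",
    "generate_monolayer",
    "default_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All simulator parameters.  Lengths share the dataset unit (um by default).

    ``align_fraction`` is the probability that a periphery-zone cell belongs to
    the shape-aligned (von Mises) component; ``kappa`` is the concentration of
    that component on the doubled-angle circle.  ``growth_day2`` is the
    fold-change in cell number at Day 2 relative to Day 0 (growth is exponential
    in between).  Aspect ratios are lognormal; cell areas are lognormal around
    ``mean_cell_area``.
    """

    fov: Tuple[float, float] = (400.0, 400.0)
    shape: ReferenceShape = dataclasses.field(
        default_factory=lambda: ReferenceShape(ShapeKind.CIRCLE, (200.0, 200.0), 300.0)
    )
    n_cells_day0: int = 250
    growth_day2: float = 1.8
    align_fraction: float = 0.7
    kappa: float = 3.0
    periphery_zone_width: Optional[float] = None  # default 0.15 * shape size
    aspect_median: float = 2.2
    aspect_sigma: float = 0.35
    mean_cell_area: float = 300.0
    area_sigma: float = 0.2
    outline_vertices: int = 48
    vertex_noise: float = 0.03
    min_spacing_factor: float = 0.7  # x mean cell diameter, centre-to-centre cap
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.align_fraction <= 1.0):
            raise ValueError("align_fraction must be in [0, 1]")
        for name in ("growth_day2", "kappa", "aspect_median", "aspect_sigma",
                     "mean_cell_area", "area_sigma", "min_spacing_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cells_day0 <= 0 or self.outline_vertices < 16:
            raise ValueError("need n_cells_day0 > 0 and outline_vertices >= 16")
        if not (0.0 <= self.vertex_noise < 0.5):
            raise ValueError("vertex_noise is a fractional radial jitter in [0, 0.5)")

    @property
    def zone_width(self) -> float:
        if self.periphery_zone_width is not None:
            return self.periphery_zone_width
        return 0.15 * self.shape.size

    @property
    def mean_cell_diameter(self) -> float:
        return 2.0 * math.sqrt(self.mean_cell_area / math.pi)

    def n_cells(self, day: int) -> int:
        """Cell count on ``day`` under the exponential growth schedule."""
        return int(round(self.n_cells_day0 * self.growth_day2 ** (day / 2.0)))


def default_config(**overrides) -> SyntheticConfig:
    """A SyntheticConfig with package defaults, selectively overridden."""
    return SyntheticConfig(**overrides)


def _local_reference_direction(shape: ReferenceShape, position) -> float:
    """Direction (deg) from which shape-relative angles are measured at a point:
    the radial direction for a circle, the nearest edge direction for polygons."""
    if shape.kind is ShapeKind.CIRCLE:
        return beta_angle(position[0] - shape.centroid[0], position[1] - shape.centroid[1])
    return shape.nearest_edge_angle(position)


def _axial_von_mises(rng: np.random.Generator, kappa: float) -> float:
    """Draw from a 180-deg-periodic von Mises centred at 0 by sampling the
    standard von Mises on the doubled angle."""
    return math.degrees(rng.vonmises(0.0, kappa)) / 2.0


def sample_orientation(
    position,
    config: SyntheticConfig,
    rng: np.random.Generator,
    uniform_only: bool = False,
) -> float:
    """Absolute orientation alpha in [0, 180) for a cell at ``position``."""
    alpha, _, _ = _sample_orientation_labelled(position, config, rng, uniform_only)
    return alpha


def _sample_orientation_labelled(position, config, rng, uniform_only=False):
    """Returns (alpha, in_zone, latent_label)."""
    shape = config.shape
    in_zone = shape.boundary_distance(position) <= config.zone_width
    if (not uniform_only) and in_zone and rng.random() < config.align_fraction:
        # shape-relative angle around 90 (radial), converted to the FoV frame
        rel = 90.0 + _axial_von_mises(rng, config.kappa)
        ref = _local_reference_direction(shape, position)
        if shape.kind is ShapeKind.CIRCLE:
            # rel = fold180(90 - (beta - alpha))  =>  alpha = beta - 90 + rel
            alpha = float(fold180(ref - 90.0 + rel))
        else:
            alpha = float(fold180(ref + rel))
        return alpha, in_zone, "aligned"
    return float(rng.uniform(0.0, 180.0)), in_zone, "uniform"


def generate_cell(
    center,
    alpha: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    cell_id: str = "cell",
    day: int = 0,
    region: str = "piston",
) -> CellOutline:
    """Polygonize one elliptical cell.

    Area is lognormal around ``mean_cell_area``; the aspect ratio is lognormal
    with median ``aspect_median`` (floored at 1); the major axis points
    along ``alpha``.  Vertices get multiplicative radial jitter, which keeps the
    polygon star-shaped about its centre and therefore simple.
    """
    area = config.mean_cell_area * math.exp(rng.normal(0.0, config.area_sigma))
    aspect = max(math.exp(rng.normal(math.log(config.aspect_median), config.aspect_sigma)), 1.0)
    a = math.sqrt(area * aspect / math.pi)  # semi-major
    b = math.sqrt(area / (math.pi * aspect))
    m = config.outline_vertices
    t = 2.0 * np.pi * np.arange(m) / m + rng.uniform(0.0, 2.0 * np.pi / m)
    ex, ey = a * np.cos(t), b * np.sin(t)
    if config.vertex_noise > 0.0:
        jitter = 1.0 + rng.uniform(-config.vertex_noise, config.vertex_noise, size=m)
        ex, ey = ex * jitter, ey * jitter
    phi = math.radians(alpha)
    c, s = math.cos(phi), math.sin(phi)
    xs = center[0] + c * ex - s * ey
    ys = center[1] + s * ex + c * ey
    return CellOutline(cell_id=cell_id, vertices=np.column_stack([xs, ys]), day=day, region=region)


def _place_centers(config: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sequential rejection sampling with a minimum centre-to-centre spacing."""
    w, h = config.fov
    spacing = config.min_spacing_factor * config.mean_cell_diameter
    sp2 = spacing * spacing
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    inv = 1.0 / spacing if spacing > 0 else 0.0
    centers: list[tuple[float, float]] = []
    max_attempts = max(500 * n, 10_000)
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise PlacementInfeasibleError(
                f"placed {len(centers)}/{n} cells in {attempts} attempts; density infeasible"
            )
        attempts += 1
        x, y = rng.uniform(0.0, w), rng.uniform(0.0, h)
        if spacing > 0:
            gi, gj = int(x * inv), int(y * inv)
            ok = True
            for ii in (gi - 1, gi, gi + 1):
                for jj in (gj - 1, gj, gj + 1):
                    for (px, py) in grid.get((ii, jj), ()):
                        if (px - x) ** 2 + (py - y) ** 2 < sp2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue
            grid.setdefault((gi, gj), []).append((x, y))
        centers.append((x, y))
    return np.asarray(centers)


def generate_monolayer(
    config: SyntheticConfig,
    day: int = 0,
    region: str = "piston",
) -> Tuple[list, pd.DataFrame]:
    """Generate one monolayer field and its ground-truth table.

    ``region="piston"`` applies the periphery-zone orientation bias of the
    config; ``region="control"`` draws every orientation uniformly, emulating a
    random area of the monolayer away from the piston.  Output is fully
    determined by ``(config, day, region)``.
    """
    if region not in ("piston", "control"):
        raise ValueError("region must be 'piston' or 'control'")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(day), 0 if region == "piston" else 1])
    )
    n = config.n_cells(day)
    centers = _place_centers(config, n, rng)
    outlines = []
    truth_rows = []
    uniform_only = region == "control"
    for i, (x, y) in enumerate(centers):
        alpha, in_zone, latent = _sample_orientation_labelled((x, y), config, rng, uniform_only)
        cell_id = f"{region}-d{day}-{i:04d}"
        outlines.append(
            generate_cell((x, y), alpha, config, rng, cell_id=cell_id, day=day, region=region)
        )
        truth_rows.append((cell_id, x, y, alpha, in_zone, latent))
    truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "x", "y", "true_alpha", "in_zone", "latent"]
    )
    truth["day"] = day
    truth["region"] = region
    return outlines, truth
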