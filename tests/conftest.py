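import numpy as np
import pytest

from pistonalign.geometry import ReferenceShape, ShapeKind
from pistonalign.morphometry import CellOutline


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def circle_shape():
    return ReferenceShape(ShapeKind.CIRCLE, (0.0, 0.0), 300.0)


@pytest.fixture
def triangle_shape():
    return ReferenceShape(ShapeKind.TRIANGLE, (0.0, 0.0), 300.0)


@pytest.fixture
def square_shape():
    return ReferenceShape(ShapeKind.SQUARE, (0.0, 0.0), 300.0)


def make_ellipse_outline(
    center=(0.0, 0.0),
    semi_major=10.0,
    semi_minor=4.0,
    angle_deg=0.0,
    n_vertices=64,
    cell_id="cell",
    day=0,
    region="piston",
    phase=0.0,
):
    """Polygonize an ellipse exactly (no noise) — the construct-then-recover oracle."""
    t = 2.0 * np.pi * np.arange(n_vertices) / n_vertices + phase
    ex, ey = semi_major * np.cos(t), semi_minor * np.sin(t)
    phi = np.radians(angle_deg)
    c, s = np.cos(phi), np.sin(phi)
    xs = center[0] + c * ex - s * ey
    ys = center[1] + s * ex + c * ey
    return CellOutline(cell_id=cell_id, vertices=np.column_stack([xs, ys]), day=day, region=region)


@pytest.fixture
def ellipse_outline():
    return make_ellipse_outline
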