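"""File formats: ImageJ ROI (binary), RoiSet zip, polygon tables, YAML configs.

Cell outlines are drawn by hand in ImageJ and saved as ``.roi`` files (magic
``Iout``) or bundled in a ``RoiSet.zip``.  The reader/writer here covers the
outline ROI types (polygon, freehand, traced) with sub-pixel float coordinates;
ImageJ stores image coordinates y-down, so importers flip to the package's
mathematical y-up frame when the image height is known.

A plain-text polygon dialect (CSV with columns ``cell_id, day, region,
vertex_index, x, y``) is supported as the interchange format for synthetic data
and for users not working from ImageJ.
"""

from __future__ import annotations

import io as _stdio
import struct
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InvalidOutlineError, NotARoiError, UnsupportedRoiTypeError
from .geometry import ReferenceShape, ShapeKind
from .morphometry import CellMorphometry, CellOutline

__all__ = [
    "Dataset",
    "read_imagej_roi",
    "write_imagej_roi",
    "read_roiset_zip",
    "write_roiset_zip",
    "read_polygon_table",
    "write_polygon_table",
    "measurements_frame",
    "load_shape",
    "load_synthetic_config",
]

_MAGIC = b"Iout"
_VERSION = 228
# ImageJ ROI type codes
_TYPE_POLYGON = 0
_TYPE_FREEHAND = 7
_TYPE_TRACED = 8
_OUTLINE_TYPES = {_TYPE_POLYGON, _TYPE_FREEHAND, _TYPE_TRACED}
_TYPE_NAMES = {1: "rectangle", 2: "oval", 3: "line", 4: "freeline", 5: "polyline",
               6: "no-roi", 9: "angle", 10: "point"}
_OPT_SUBPIXEL = 128
_HEADER_SIZE = 64


@dataclass
class Dataset:
    """A collection of outlines and reference shapes sharing one length unit."""

    outlines: list = field(default_factory=list)
    shapes: list = field(default_factory=list)
    units: str = "um"
    image_height: Optional[float] = None

    def validate(self) -> "Dataset":
        for s in self.shapes:
            if s.units != self.units:
                raise ConfigurationError(
                    f"shape units {s.units!r} differ from dataset units {self.units!r}"
                )
        for o in self.outlines:
            o.vertex_array  # raises on non-finite coordinates
        return self


# ---------------------------------------------------------------------------
# ImageJ .roi binary format
# ---------------------------------------------------------------------------

def write_imagej_roi(outline: CellOutline, image_height: Optional[float] = None) -> bytes:
    """Encode an outline as an ImageJ polygon ROI with sub-pixel coordinates.

    If ``image_height`` is given the outline (mathematical y-up) is converted to
    the image's y-down frame on write; otherwise coordinates are written as-is.
    The encoding is canonical, so write -> read -> write is byte-stable.
    """
    v = outline.vertex_array.copy()
    if image_height is not None:
        v[:, 1] = image_height - v[:, 1]
    n = v.shape[0]
    # deterministic integer grid: round half up, offsets relative to bounding box
    ints = np.floor(v + 0.5).astype(np.int32)
    left, top = int(ints[:, 0].min()), int(ints[:, 1].min())
    right, bottom = int(ints[:, 0].max()), int(ints[:, 1].max())
    buf = bytearray(_HEADER_SIZE + 4 * n + 8 * n)
    struct.pack_into(">4sh", buf, 0, _MAGIC, _VERSION)
    buf[6] = _TYPE_POLYGON
    struct.pack_into(">4h", buf, 8, top, left, bottom, right)
    struct.pack_into(">H", buf, 16, n)
    struct.pack_into(">h", buf, 50, _OPT_SUBPIXEL)
    off = _HEADER_SIZE
    for i in range(n):
        struct.pack_into(">h", buf, off + 2 * i, int(ints[i, 0]) - left)
        struct.pack_into(">h", buf, off + 2 * (n + i), int(ints[i, 1]) - top)
    off += 4 * n
    for i in range(n):
        struct.pack_into(">f", buf, off + 4 * i, float(v[i, 0]))
        struct.pack_into(">f", buf, off + 4 * (n + i), float(v[i, 1]))
    return bytes(buf)


def read_imagej_roi(
    data: bytes,
    cell_id: str = "roi",
    day: int = 0,
    region: str = "piston",
    image_height: Optional[float] = None,
) -> CellOutline:
    """Decode an ImageJ ``.roi`` byte stream into a :class:`CellOutline`.

    Accepts polygon, freehand and traced ROI types; sub-pixel float coordinates
    are used when present, integer coordinates otherwise.  With ``image_height``
    the y axis is flipped from the image frame to the mathematical frame.
    """
    if len(data) < _HEADER_SIZE or data[:4] != _MAGIC:
        raise NotARoiError("byte stream does not start with the ImageJ ROI magic 'Iout'")
    version = struct.unpack_from(">h", data, 4)[0]
    roi_type = data[6]
    if roi_type not in _OUTLINE_TYPES:
        name = _TYPE_NAMES.get(roi_type, f"type {roi_type}")
        raise UnsupportedRoiTypeError(f"unsupported ROI type: {name}")
    top, left, _bottom, _right = struct.unpack_from(">4h", data, 8)
    n = struct.unpack_from(">H", data, 16)[0]
    if n < 3:
        raise InvalidOutlineError(f"ROI {cell_id!r} has {n} vertices; an outline needs >= 3")
    options = struct.unpack_from(">h", data, 50)[0]
    subpixel = bool(options & _OPT_SUBPIXEL) and version >= 222
    off = _HEADER_SIZE
    if subpixel and len(data) >= off + 4 * n + 8 * n:
        xs = np.frombuffer(data, dtype=">f4", count=n, offset=off + 4 * n).astype(float)
        ys = np.frombuffer(data, dtype=">f4", count=n, offset=off + 4 * n + 4 * n).astype(float)
    else:
        xs = np.frombuffer(data, dtype=">i2", count=n, offset=off).astype(float) + left
        ys = np.frombuffer(data, dtype=">i2", count=n, offset=off + 2 * n).astype(float) + top
    if image_height is not None:
        ys = image_height - ys
    return CellOutline(cell_id=cell_id, vertices=tuple(zip(xs, ys)), day=day, region=region)


def write_roiset_zip(
    outlines: Iterable[CellOutline],
    path: Union[str, Path],
    image_height: Optional[float] = None,
) -> None:
    """Write outlines to a RoiSet zip; entry names carry the cell ids."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for outline in outlines:
            info = zipfile.ZipInfo(f"{outline.cell_id}.roi", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, write_imagej_roi(outline, image_height=image_height))


def read_roiset_zip(
    path: Union[str, Path, bytes],
    day: int = 0,
    region: str = "piston",
    image_height: Optional[float] = None,
) -> list:
    """Read all ``.roi`` entries of a RoiSet zip; entry names become cell ids."""
    src = _stdio.BytesIO(path) if isinstance(path, bytes) else path
    outlines = []
    with zipfile.ZipFile(src) as zf:
        for name in sorted(zf.namelist()):
            if not name.lower().endswith(".roi"):
                continue
            cell_id = Path(name).stem
            outlines.append(
                read_imagej_roi(zf.read(name), cell_id=cell_id, day=day,
                                region=region, image_height=image_height)
            )
    return outlines


# ---------------------------------------------------------------------------
# Plain polygon tables
# ---------------------------------------------------------------------------

_POLY_COLUMNS = ["cell_id", "day", "region", "vertex_index", "x", "y"]


def read_polygon_table(source) -> list:
    """Read outlines from the CSV polygon dialect.

    Expects columns ``cell_id, day, region, vertex_index, x, y``; rows are
    grouped by ``cell_id`` and ordered by ``vertex_index``.  Duplicate vertex
    indices, fewer than 3 vertices, or self-intersecting polygons are errors; an
    empty table yields an empty list with a warning.
    """
    df = pd.read_csv(source)
    missing = [c for c in _POLY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"polygon table is missing columns: {missing}")
    if df.empty:
        warnings.warn("polygon table contains no rows", stacklevel=2)
        return []
    if df.duplicated(subset=["cell_id", "vertex_index"]).any():
        dupes = df[df.duplicated(subset=["cell_id", "vertex_index"])]["cell_id"].unique()
        raise InvalidOutlineError(f"duplicate (cell_id, vertex_index) rows for: {list(dupes)}")
    outlines = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("vertex_index")
        outline = CellOutline(
            cell_id=str(cell_id),
            vertices=tuple(zip(grp["x"].astype(float), grp["y"].astype(float))),
            day=int(grp["day"].iloc[0]),
            region=str(grp["region"].iloc[0]),
        )
        outlines.append(outline.validate())
    return outlines


def write_polygon_table(outlines: Iterable[CellOutline], path=None) -> pd.DataFrame:
    """Serialize outlines to the CSV polygon dialect (returned; written if ``path``)."""
    rows = []
    for o in outlines:
        for j, (x, y) in enumerate(o.vertex_array):
            rows.append((o.cell_id, o.day, o.region, j, x, y))
    df = pd.DataFrame(rows, columns=_POLY_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def measurements_frame(morphometries: Sequence[CellMorphometry]) -> pd.DataFrame:
    """Tabulate morphometry output (one row per cell)."""
    rows = [
        {
            "cell_id": m.cell_id,
            "day": m.day,
            "region": m.region,
            "centroid_x": m.centroid[0],
            "centroid_y": m.centroid[1],
            "alpha_deg": m.alpha,
            "major": m.major_len,
            "minor": m.minor_len,
            "aspect": m.aspect,
            "orientation_defined": m.orientation_defined,
        }
        for m in morphometries
    ]
    return pd.DataFrame(rows, columns=["cell_id", "day", "region", "centroid_x", "centroid_y",
                                       "alpha_deg", "major", "minor", "aspect",
                                       "orientation_defined"])


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def shape_from_dict(d: dict) -> ReferenceShape:
    return ReferenceShape(
        kind=ShapeKind(d["kind"]),
        centroid=(float(d["centroid_x"]), float(d["centroid_y"])),
        size=float(d["size"]),
        rotation_k=float(d.get("rotation_k", 0.0)),
        units=str(d.get("units", "um")),
    )


def load_shape(path: Union[str, Path]) -> ReferenceShape:
    """Load a reference-shape description from YAML/JSON."""
    with open(path) as fh:
        return shape_from_dict(yaml.safe_load(fh))


def load_synthetic_config(path: Union[str, Path]):
    """Load a :class:`~pistonalign.simulate.SyntheticConfig` from YAML."""
    from .simulate import SyntheticConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "shape" in raw:
        raw["shape"] = shape_from_dict(raw["shape"])
    if "fov" in raw:
        raw["fov"] = tuple(raw["fov"])
    return SyntheticConfig(**raw)
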