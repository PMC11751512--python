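"""Exception types raised across the package."""


class PistonAlignError(Exception):
    """Base class for all package-specific errors."""


class InvalidOutlineError(PistonAlignError):
    """Cell outline is degenerate: fewer than 3 vertices, zero area, or self-intersecting."""


class UnsupportedShapeKindError(PistonAlignError):
    """Operation requires a polygonal reference shape but received a circle (or unknown kind)."""


class CellAtCentroidError(PistonAlignError):
    """Cell centroid coincides with the reference-shape centroid; the position angle is undefined."""


class IrreconcilableRowError(PistonAlignError):
    """Printed percentages and group size cannot be inverted to integer counts that sum to n."""


class DegeneratePoolError(PistonAlignError):
    """Pooled proportion is exactly 0 or 1 with unequal percentages; the t statistic is undefined."""


class PlacementInfeasibleError(PistonAlignError):
    """Rejection sampling could not place a geometry (or cell) under the stated constraints."""


class NotARoiError(PistonAlignError):
    """Byte stream does not start with the ImageJ ROI magic 'Iout'."""


class UnsupportedRoiTypeError(PistonAlignError):
    """ImageJ ROI type is not an outline (polygon/freehand/traced)."""


class ConfigurationError(PistonAlignError):
    """Inconsistent configuration, e.g. mixed units between outlines and shapes."""
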