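"""Small helpers for axial (180 degree-periodic) angle arithmetic in degrees."""

from __future__ import annotations

import numpy as np


def fold180(angle_deg):
    """Fold an angle (or array of angles) into the axial range [0, 180).

    Orientations are axial data: a cell axis at 190 deg is the same axis as 10 deg.
    """
    return np.mod(angle_deg, 180.0)


def axial_difference(a_deg, b_deg):
    """Unsigned axial distance between two orientations, in [0, 90]."""
    d = np.mod(a_deg - b_deg, 180.0)
    return np.minimum(d, 180.0 - d)
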