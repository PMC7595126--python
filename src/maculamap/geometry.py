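"""Frame conventions and small planar-geometry helpers.

All en-face coordinates are micrometres with the origin at the foveal centre,
in right-eye format: x increases toward the optic disc (nasal), y increases
toward superior retina.

Two frames are used:

* the **field frame** (tilt 0): axes aligned with the perimetric / head frame;
* the **scan frame**: the acquisition frame, rotated so its x axis runs along
  the fovea–optic-disc axis.

The fovea-to-disc tilt angle is positive when the disc centre lies *below*
the horizontal through the fovea (right-eye format).  With y pointing
superior this makes the scan x axis a *clockwise* rotation of the field
x axis by ``tilt_deg``, hence coordinates of a fixed retinal point transform
as ``p_scan = R(+tilt) @ p_field`` where ``R`` is the usual counter-clockwise
rotation matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_matrix",
    "rotate_xy",
    "field_to_scan",
    "scan_to_field",
]


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """Counter-clockwise 2-D rotation matrix for ``angle_deg`` degrees."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def rotate_xy(xy, angle_deg: float) -> np.ndarray:
    """Rotate points counter-clockwise by ``angle_deg``.

    ``xy`` is (..., 2); returns the same shape.
    """
    xy = np.asarray(xy, dtype=float)
    return xy @ rotation_matrix(angle_deg).T


def field_to_scan(xy_um, tilt_deg: float) -> np.ndarray:
    """Coordinates of fixed retinal points, field frame -> scan frame."""
    return rotate_xy(xy_um, +tilt_deg)


def scan_to_field(xy_um, tilt_deg: float) -> np.ndarray:
    """Coordinates of fixed retinal points, scan frame -> field frame."""
    return rotate_xy(xy_um, -tilt_deg)
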