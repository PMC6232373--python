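"""Axial-angle arithmetic.

Convention used throughout the package: orientations are *axial* (lines,
not vectors), expressed in degrees on the half-open interval [-90, 90),
measured counterclockwise from the +x axis.  Images are row-major with
origin top-left, so the +x axis is the column axis and +y points *up*,
i.e. against the row index.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_axial",
    "axial_difference",
    "angle_from_vector",
    "unit_vector",
]


def wrap_axial(angle_deg):
    """Wrap an angle (degrees) into the axial interval [-90, 90)."""
    return (np.asarray(angle_deg) + 90.0) % 180.0 - 90.0


def axial_difference(a_deg, b_deg):
    """Smallest separation between two axial angles, in [0, 90].

    Equals ``min_k |a - b + 180 k|`` — the 180-degree periodicity of a
    line orientation is taken into account.
    """
    d = np.abs(wrap_axial(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)))
    # wrap_axial maps the ±90 boundary to -90; |.| then yields 90, correct.
    out = np.where(d > 90.0, 180.0 - d, d)
    if np.ndim(out) == 0:
        return float(out)
    return out


def angle_from_vector(d_row, d_col):
    """Axial angle (deg in [-90, 90)) of the direction (d_row, d_col).

    Rows grow downwards, hence the sign flip on ``d_row``.
    """
    ang = np.degrees(np.arctan2(-np.asarray(d_row, dtype=float), np.asarray(d_col, dtype=float)))
    out = wrap_axial(ang)
    if np.ndim(out) == 0:
        return float(out)
    return out


def unit_vector(angle_deg):
    """(d_row, d_col) unit vector pointing along an axial angle."""
    rad = np.deg2rad(angle_deg)
    return -np.sin(rad), np.cos(rad)
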