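"""Circular angle arithmetic.

Azimuth convention used throughout the package: degrees, positive clockwise
(to the listener's right), wrapped into [-180, 180).  Elevation is degrees
above the horizontal plane, limited to the spherical cap [-40, 90] covered
by typical HRTF measurement sets.
"""

from __future__ import annotations

import numpy as np

ELEVATION_MIN = -40.0
ELEVATION_MAX = 90.0


def wrap_deg(angle):
    """Wrap angle(s) in degrees onto [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def angular_difference(a, b):
    """Shortest signed arc from ``b`` to ``a`` in degrees (positive clockwise)."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def clip_elevation(elevation):
    """Clip elevation(s) to the spherical-cap coverage [-40, 90] degrees."""
    return np.clip(np.asarray(elevation, dtype=float), ELEVATION_MIN, ELEVATION_MAX)
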