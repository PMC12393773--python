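"""Circular arithmetic for 180°-periodic orientations.

Conventions used across the package:

* orientations live in the half-open interval ``[0, 180)`` degrees;
* relative orientations (differences) are wrapped into ``(-90, 90]``;
* positive relative orientation = counterclockwise, negative = clockwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_orientation", "relative_orientation"]


def wrap_orientation(theta):
    """Wrap orientation(s) in degrees into [0, 180)."""
    return np.asarray(theta, dtype=float) % 180.0


def relative_orientation(a, b):
    """Signed circular difference ``a - b`` wrapped into (-90, 90].

    Positive values mean ``a`` is counterclockwise of ``b``; the boundary
    difference of 90° maps to +90 (never -90). Accepts scalars or arrays
    (broadcast); NaN propagates.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    out = np.where(d > 90.0, d - 180.0, d)
    if out.ndim == 0:
        return float(out)
    return out
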