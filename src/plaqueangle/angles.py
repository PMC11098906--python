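"""Shared angular conventions.

Every module measures angles the same way: 0 degrees along the +x image
axis, increasing counter-clockwise in standard image display (y pointing
down on screen), so the mathematical angle is ``atan2(-(y - cy), x - cx)``.
Degree bins are half-open ``[a, a+1)`` for integer ``a`` in ``[0, 360)``.
A pixel exactly at the reference center has an undefined angle and is
assigned bin 0 by convention.

Arcs are half-open intervals ``[start, end)`` in degrees.  ``end < start``
denotes an arc wrapping through 0 degrees; the full circle is written
``(0, 360)``.
"""

from __future__ import annotations

import numpy as np

N_ANGLE_BINS = 360


def pixel_angles_deg(shape: tuple[int, int], center_xy: tuple[float, float]) -> np.ndarray:
    """Per-pixel angle in degrees ``[0, 360)`` about ``center_xy`` for an
    image of the given ``(height, width)`` shape."""
    h, w = shape
    cx, cy = center_xy
    y, x = np.mgrid[0:h, 0:w]
    ang = np.degrees(np.arctan2(-(y - cy), x - cx))
    return np.mod(ang, 360.0)


def pixel_angle_bins(shape: tuple[int, int], center_xy: tuple[float, float]) -> np.ndarray:
    """Integer degree bin of every pixel about ``center_xy``.

    Bins are ``floor(angle)`` clipped into ``[0, 359]`` (the clip only
    guards against ``floor(359.999...) == 360`` from rounding).
    """
    bins = np.floor(pixel_angles_deg(shape, center_xy)).astype(np.int64)
    return np.clip(bins, 0, N_ANGLE_BINS - 1)


def pixel_radii(shape: tuple[int, int], center_xy: tuple[float, float]) -> np.ndarray:
    """Per-pixel Euclidean distance (pixels) from ``center_xy``."""
    h, w = shape
    cx, cy = center_xy
    y, x = np.mgrid[0:h, 0:w]
    return np.hypot(x - cx, y - cy)


def arc_width_deg(start_deg: float, end_deg: float) -> float:
    """Angular width of the half-open arc ``[start, end)``, wrap-aware."""
    w = end_deg - start_deg
    if w <= 0:
        w += 360.0
    return w


def arc_bins(start_deg: float, end_deg: float) -> np.ndarray:
    """Integer degree bins covered by the arc ``[start, end)``.

    A bin ``a`` is covered when the bin interval ``[a, a+1)`` intersects
    the arc, evaluated on bin start points: bins ``ceil-free`` from
    ``floor(start)`` while the bin start lies in the arc.  For integer
    endpoints this is exactly ``start .. end-1`` (mod 360).
    """
    start = float(start_deg) % 360.0
    width = arc_width_deg(start_deg, end_deg)
    first = int(np.floor(start))
    n = int(np.ceil(start + width)) - first
    n = min(n, N_ANGLE_BINS)
    return np.mod(np.arange(first, first + n), N_ANGLE_BINS)


def arc_mask(start_deg: float, end_deg: float) -> np.ndarray:
    """Boolean occupancy vector of length 360 for the arc ``[start, end)``."""
    m = np.zeros(N_ANGLE_BINS, dtype=bool)
    m[arc_bins(start_deg, end_deg)] = True
    return m


def circular_iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Intersection-over-union of two angular intervals on the circle.

    Intervals are ``(start, end)`` half-open degree pairs, wrap allowed.
    Computed exactly on continuous arcs (not bins).
    """
    sa, wa = float(a[0]) % 360.0, arc_width_deg(*a)
    sb, wb = float(b[0]) % 360.0, arc_width_deg(*b)
    if wa >= 360.0 and wb >= 360.0:
        return 1.0
    # Unroll interval b relative to a on the line; wrap means b may start
    # before or after a by up to 360 degrees.
    inter = 0.0
    for shift in (-360.0, 0.0, 360.0):
        lo = max(sa, sb + shift)
        hi = min(sa + wa, sb + shift + wb)
        inter += max(0.0, hi - lo)
    inter = min(inter, wa, wb)
    union = wa + wb - inter
    return inter / union if union > 0 else 0.0
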