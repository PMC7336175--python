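"""Polar geometry on the axial (y, x) slice plane.

One set of conventions shared by every module:

* arrays are indexed ``(z, y, x)`` with z along the tooth/post long axis;
* the azimuthal angle is measured in the (x, y) slice plane, 0 deg at the
  +x axis, increasing counter-clockwise (mathematical convention with y as
  the second Cartesian axis), in ``[0, 360)``;
* radial intervals and arcs are half-open: ``r_in <= r < r_out`` and
  ``start <= theta < start + extent`` (modulo 360).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "radius_map_um",
    "angle_map_deg",
    "annulus_mask",
    "arc_mask",
    "circular_union",
    "interval_overlap_deg",
]


def radius_map_um(shape_yx, center, voxel_um: float = 1.0) -> np.ndarray:
    """Per-pixel distance (µm) from a sub-pixel ``(cy, cx)`` center."""
    ny, nx = shape_yx
    cy, cx = center
    y = np.arange(ny, dtype=float)[:, None] - cy
    x = np.arange(nx, dtype=float)[None, :] - cx
    return np.hypot(y, x) * voxel_um


def angle_map_deg(shape_yx, center) -> np.ndarray:
    """Per-pixel azimuth in degrees, in [0, 360)."""
    ny, nx = shape_yx
    cy, cx = center
    y = np.arange(ny, dtype=float)[:, None] - cy
    x = np.arange(nx, dtype=float)[None, :] - cx
    theta = np.degrees(np.arctan2(y, x))
    return np.mod(theta, 360.0)


def annulus_mask(shape_yx, center, r_in_um, r_out_um, voxel_um: float = 1.0) -> np.ndarray:
    """Boolean mask of pixels with ``r_in_um <= r < r_out_um``."""
    if r_out_um <= r_in_um:
        raise ValueError(f"annulus requires r_in < r_out, got [{r_in_um}, {r_out_um})")
    r = radius_map_um(shape_yx, center, voxel_um)
    return (r >= r_in_um) & (r < r_out_um)


def arc_mask(shape_yx, center, start_deg, extent_deg) -> np.ndarray:
    """Boolean mask of pixels with azimuth in ``[start, start + extent)`` mod 360."""
    if not 0 < extent_deg <= 360.0:
        raise ValueError(f"arc extent must be in (0, 360], got {extent_deg}")
    theta = angle_map_deg(shape_yx, center)
    return np.mod(theta - start_deg, 360.0) < extent_deg


def circular_union(intervals) -> list[tuple[float, float]]:
    """Union of ``(start, extent)`` degree intervals as disjoint linear segments.

    Returns segments ``(a, b)`` with ``0 <= a < b <= 360`` covering the same
    set of angles modulo 360.
    """
    segments = []
    for start, extent in intervals:
        if extent <= 0:
            continue
        extent = min(extent, 360.0)
        s = np.mod(start, 360.0)
        e = s + extent
        if e <= 360.0:
            segments.append((s, e))
        else:
            segments.append((s, 360.0))
            segments.append((0.0, e - 360.0))
    if not segments:
        return []
    segments.sort()
    merged = [list(segments[0])]
    for a, b in segments[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(seg) for seg in merged]


def interval_overlap_deg(a, b, segments) -> float:
    """Total length of ``[a, b)`` covered by disjoint linear ``segments``."""
    total = 0.0
    for s, e in segments:
        total += max(0.0, min(b, e) - max(a, s))
    return total
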