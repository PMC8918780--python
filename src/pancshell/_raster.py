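"""Analytic rasterization of balls, capsules and tubes into anisotropic voxel grids.

Voxel centers sit at ``index * spacing``; a voxel belongs to a shape iff its
center lies inside the analytic shape, which keeps voxel-count oracles exact.
Positions are µm ``(x, y, z)``; arrays are ``(z, y, x)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["paint_ball", "paint_capsule", "paint_polyline_tube"]


def _bbox_slices(shape, spacing, lo_xyz, hi_xyz):
    lo_zyx = np.asarray(lo_xyz, dtype=float)[::-1]
    hi_zyx = np.asarray(hi_xyz, dtype=float)[::-1]
    sp = np.asarray(spacing, dtype=float)
    i0 = np.maximum(np.floor(lo_zyx / sp).astype(int), 0)
    i1 = np.minimum(np.ceil(hi_zyx / sp).astype(int) + 1, np.asarray(shape))
    if np.any(i0 >= i1):
        return None
    return tuple(slice(a, b) for a, b in zip(i0, i1))


def _coord_grids(slices, spacing):
    dz, dy, dx = spacing
    zz = (np.arange(slices[0].start, slices[0].stop) * dz)[:, None, None]
    yy = (np.arange(slices[1].start, slices[1].stop) * dy)[None, :, None]
    xx = (np.arange(slices[2].start, slices[2].stop) * dx)[None, None, :]
    return zz, yy, xx


def paint_ball(data: np.ndarray, spacing, center_xyz, radius: float) -> None:
    """Set to True all voxels whose center lies within ``radius`` of the point."""
    c = np.asarray(center_xyz, dtype=float)
    sl = _bbox_slices(data.shape, spacing, c - radius, c + radius)
    if sl is None:
        return
    zz, yy, xx = _coord_grids(sl, spacing)
    d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
    data[sl] |= d2 <= radius * radius


def paint_capsule(data: np.ndarray, spacing, p0_xyz, p1_xyz, radius: float) -> None:
    """Set voxels within ``radius`` of the segment p0-p1 (a capsule, caps included)."""
    p0 = np.asarray(p0_xyz, dtype=float)
    p1 = np.asarray(p1_xyz, dtype=float)
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    sl = _bbox_slices(data.shape, spacing, lo, hi)
    if sl is None:
        return
    zz, yy, xx = _coord_grids(sl, spacing)
    d = p1 - p0
    L2 = float(d @ d)
    px, py, pz = xx - p0[0], yy - p0[1], zz - p0[2]
    if L2 == 0.0:
        d2 = px * px + py * py + pz * pz
    else:
        t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / L2, 0.0, 1.0)
        d2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    data[sl] |= d2 <= radius * radius


def paint_polyline_tube(data: np.ndarray, spacing, points_xyz: np.ndarray, radius: float) -> None:
    """Union of capsules along a polyline — a constant-radius tube."""
    pts = np.asarray(points_xyz, dtype=float).reshape(-1, 3)
    if len(pts) == 1:
        paint_ball(data, spacing, pts[0], radius)
        return
    for a, b in zip(pts[:-1], pts[1:]):
        paint_capsule(data, spacing, a, b, radius)
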