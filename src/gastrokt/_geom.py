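"""Internal geometry helpers shared by the phantom and motility modules."""

from __future__ import annotations

import numpy as np


def polyline_geometry(points: np.ndarray, polyline: np.ndarray):
    """Arc-length position and radial distance of points relative to a polyline.

    Returns ``(s, dist)``: the arc-length of the closest (segment-clamped)
    projection of each point onto the polyline, and the distance to it.
    """
    points = np.asarray(points, float)
    polyline = np.asarray(polyline, float)
    best_d2 = np.full(points.shape[0], np.inf)
    best_s = np.zeros(points.shape[0])
    s0 = 0.0
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        seg_len = float(np.linalg.norm(ab))
        if seg_len == 0:
            continue
        ap = points - a
        t = np.clip(ap @ ab / (seg_len**2), 0.0, 1.0)
        closest = a + t[:, None] * ab
        d2 = np.sum((points - closest) ** 2, axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_s[better] = s0 + t[better] * seg_len
        s0 += seg_len
    return best_s, np.sqrt(best_d2)


def polyline_length(polyline: np.ndarray) -> float:
    pts = np.asarray(polyline, float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def ellipsoid_inside(points: np.ndarray, center, semiaxes) -> np.ndarray:
    q = (np.asarray(points, float) - np.asarray(center, float)) / np.asarray(semiaxes, float)
    return np.sum(q * q, axis=1) <= 1.0


def point_at_arclength(polyline: np.ndarray, s: float) -> np.ndarray:
    """Point at arc-length ``s`` along a polyline (clamped to its ends)."""
    pts = np.asarray(polyline, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(i, len(seg) - 1)
    frac = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    return pts[i] + frac * (pts[i + 1] - pts[i])


def voxel_centers(grid, voxel_size) -> np.ndarray:
    """Physical centres (mm) of all voxels, shape (n_voxels, 3), C order."""
    axes = [(np.arange(n) + 0.5) * d for n, d in zip(grid, voxel_size)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
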