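"""Minimum-area enclosing rectangle of a planar point set.

The optimal rectangle shares a side direction with some edge of the convex
hull, so the search enumerates hull edges ("rotating calipers"): for each
edge direction, the axis-aligned extents in the rotated frame give a
candidate rectangle, and the smallest-area candidate is exact — no angular
discretization is involved.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError


def _principal_direction(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    # right singular vector of the largest singular value
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    return d / np.linalg.norm(d)


def min_area_rect_points(pts: np.ndarray):
    """Smallest-area rectangle enclosing 2D points.

    Parameters
    ----------
    pts : (n, 2) array of point coordinates (any consistent unit).

    Returns
    -------
    center : (2,) array — rectangle center.
    extents : (e1, e2) — side lengths along ``direction`` and its normal.
    direction : (2,) unit vector of the first side.

    Degenerate inputs (single point, collinear points) yield a rectangle of
    zero width along the normal direction.
    """
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) point array")
    if len(pts) == 0:
        raise ValueError("empty point set")
    if len(pts) == 1:
        return pts[0].copy(), (0.0, 0.0), np.array([1.0, 0.0])

    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:  # flat (collinear) input
        d = _principal_direction(pts)
        proj = pts @ d
        center = ((proj.max() + proj.min()) / 2) * d + _off_axis_center(pts, d)
        return center, (float(proj.max() - proj.min()), 0.0), d

    best = None
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.linalg.norm(edges, axis=1)
    for edge, elen in zip(edges, lengths):
        if elen == 0:
            continue
        d = edge / elen
        n = np.array([-d[1], d[0]])
        pd = verts @ d
        pn = verts @ n
        e1, e2 = pd.max() - pd.min(), pn.max() - pn.min()
        area = e1 * e2
        if best is None or area < best[0] - 1e-12 * max(best[0], 1.0):
            center = ((pd.max() + pd.min()) / 2) * d + ((pn.max() + pn.min()) / 2) * n
            best = (area, center, (float(e1), float(e2)), d)
    _, center, extents, d = best
    return center, extents, d


def _off_axis_center(pts: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = np.array([-d[1], d[0]])
    pn = pts @ n
    return ((pn.max() + pn.min()) / 2) * n


def brute_force_min_area(pts: np.ndarray, step_deg: float = 0.1) -> float:
    """Reference minimum rectangle area over a dense rotation grid.

    Independent oracle for :func:`min_area_rect_points`: sweep orientations in
    ``step_deg`` increments and take the smallest axis-aligned bounding-box
    area in each rotated frame.
    """
    pts = np.asarray(pts, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    cos, sin = np.cos(angles), np.sin(angles)
    x = pts[:, 0][:, None] * cos - pts[:, 1][:, None] * sin
    y = pts[:, 0][:, None] * sin + pts[:, 1][:, None] * cos
    areas = (x.max(axis=0) - x.min(axis=0)) * (y.max(axis=0) - y.min(axis=0))
    return float(areas.min())


__all__ = ["min_area_rect_points", "brute_force_min_area"]
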