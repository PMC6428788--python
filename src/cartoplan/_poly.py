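"""Internal 2-D polyline helpers for closed contours.

Contours are stored as ``(n, 2)`` arrays of ``[x, y]`` mm without a repeated
first point; closure is implicit everywhere.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LinearRing, Point, Polygon


def as_open_ring(points: np.ndarray) -> np.ndarray:
    """Return the contour without a duplicated closing point."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) array of [x, y] mm")
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def is_simple_ring(points: np.ndarray) -> bool:
    """True if the implicitly-closed contour does not self-intersect."""
    pts = as_open_ring(points)
    if len(pts) < 3:
        return False
    return LinearRing(pts).is_valid


def ring_segment_lengths(pts: np.ndarray) -> np.ndarray:
    """Length of each closed-ring segment i -> i+1 (wrapping)."""
    nxt = np.roll(pts, -1, axis=0)
    return np.linalg.norm(nxt - pts, axis=1)


def ring_perimeter(pts: np.ndarray) -> float:
    return float(ring_segment_lengths(pts).sum())


def resample_ring(points: np.ndarray, n: int, start_angle: float = 0.0,
                  dense: int = 4096) -> np.ndarray:
    """Resample a closed contour to ``n`` equal-arc-length points.

    The first output point is where the ray from the contour centroid at
    ``start_angle`` (radians, CCW from +x) crosses the contour, so that rings
    from adjacent slices share an angular origin and can be stitched by index.
    """
    pts = as_open_ring(points)
    if len(pts) < 3:
        raise ValueError("contour needs at least 3 distinct points")
    # densify first so both the start-crossing and the equal-arc sampling are
    # insensitive to the input vertex distribution
    seg = ring_segment_lengths(pts)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s_dense = np.linspace(0.0, total, dense, endpoint=False)
    closed = np.vstack([pts, pts[:1]])
    x = np.interp(s_dense, cum, closed[:, 0])
    y = np.interp(s_dense, cum, closed[:, 1])
    dpts = np.column_stack([x, y])

    centroid = dpts.mean(axis=0)
    rel = dpts - centroid
    ang = np.mod(np.arctan2(rel[:, 1], rel[:, 0]) - start_angle, 2.0 * np.pi)
    start = int(np.argmin(ang))
    dpts = np.roll(dpts, -start, axis=0)

    seg_d = ring_segment_lengths(dpts)
    cum_d = np.concatenate([[0.0], np.cumsum(seg_d)])
    s_out = np.linspace(0.0, cum_d[-1], n, endpoint=False)
    closed_d = np.vstack([dpts, dpts[:1]])
    return np.column_stack([
        np.interp(s_out, cum_d, closed_d[:, 0]),
        np.interp(s_out, cum_d, closed_d[:, 1]),
    ])


def ray_ring_intersection(origin: np.ndarray, direction: np.ndarray,
                          ring: np.ndarray) -> float | None:
    """Smallest positive ray parameter where ``origin + s*direction`` hits the ring.

    Returns ``None`` when the ray misses every segment.
    """
    p = np.asarray(ring, dtype=float)
    q = np.roll(p, -1, axis=0)
    d = np.asarray(direction, dtype=float)
    o = np.asarray(origin, dtype=float)
    e = q - p  # segment vectors
    # solve o + s d = p + u e ; cross products in 2-D
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    w = p - o
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
        u = (w[:, 0] * d[1] - w[:, 1] * d[0]) / denom
    valid = np.isfinite(s) & np.isfinite(u) & (s > 1e-9) & (u >= 0.0) & (u < 1.0)
    if not np.any(valid):
        return None
    return float(np.min(s[valid]))


def project_point_to_ring(point: np.ndarray, ring: np.ndarray):
    """Closest point on the implicitly-closed polyline to ``point``.

    Returns ``(closest_xy, arc_length_position, distance)`` where the arc
    position is measured from ring vertex 0 along increasing vertex index.
    """
    p = np.asarray(ring, dtype=float)
    q = np.roll(p, -1, axis=0)
    e = q - p
    seg_len2 = np.einsum("ij,ij->i", e, e)
    pt = np.asarray(point, dtype=float)[:2]
    t = np.clip(np.einsum("ij,ij->i", pt - p, e) / np.maximum(seg_len2, 1e-30), 0.0, 1.0)
    proj = p + t[:, np.newaxis] * e
    d2 = np.einsum("ij,ij->i", proj - pt, proj - pt)
    i = int(np.argmin(d2))
    seg = np.sqrt(seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return proj[i], float(cum[i] + t[i] * seg[i]), float(np.sqrt(d2[i]))


def point_in_ring(point: np.ndarray, ring: np.ndarray) -> bool:
    return Polygon(as_open_ring(ring)).contains(Point(point[0], point[1]))
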