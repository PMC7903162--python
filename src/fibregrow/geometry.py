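"""Capsule-chain geometry.

A grown fibre is geometrically a chain of capsules: spheres of linearly
interpolated radius swept along consecutive skeleton segments.  All
clearance logic (node updates, overlap audits, radius recovery, voxel
density) reduces to signed distances from points to these swept surfaces.

The swept-sphere surface with a linearly varying radius is a cone frustum
capped by spheres; we approximate its distance by ``d(p, segment) - r(t*)``
with ``t*`` the closest parameter on the segment.  The approximation is
exact for constant radii and errs by O(|r1 - r0|) otherwise, well below the
skeleton discretisation scale.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "segment_closest_param",
    "points_segment_distance",
    "capsule_chain_distance",
    "polyline_arclength",
]


def segment_closest_param(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Clamped parameter t in [0, 1] of the closest point on segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.zeros(len(points))
    t = (points - a) @ ab / denom
    return np.clip(t, 0.0, 1.0)


def points_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    t = segment_closest_param(points, a, b)
    closest = a + t[:, None] * (b - a)
    return np.linalg.norm(points - closest, axis=1)


def capsule_chain_distance(
    points: np.ndarray,
    skeleton: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    """Signed distance from each point to the fibre surface (negative inside).

    Parameters
    ----------
    points : (M, 3) array
    skeleton : (S, 3) array of ordered skeleton positions
    radii : (S,) per-point radii, linearly interpolated along segments
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    skeleton = np.asarray(skeleton, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if skeleton.ndim != 2 or len(skeleton) == 0:
        raise ValueError("skeleton must be a non-empty (S, 3) array")
    if len(skeleton) == 1:
        return np.linalg.norm(points - skeleton[0], axis=1) - radii[0]

    best = np.full(len(points), np.inf)
    a = skeleton[:-1]
    b = skeleton[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    for s in range(len(a)):
        if denom[s] == 0.0:
            t = np.zeros(len(points))
        else:
            t = np.clip((points - a[s]) @ ab[s] / denom[s], 0.0, 1.0)
        closest = a[s] + t[:, None] * ab[s]
        r = radii[s] + t * (radii[s + 1] - radii[s])
        d = np.linalg.norm(points - closest, axis=1) - r
        np.minimum(best, d, out=best)
    return best


def capsule_chain_closest(
    points: np.ndarray,
    skeleton: np.ndarray,
    radii: np.ndarray,
):
    """Signed surface distance plus the closest axis point for each query.

    Returns ``(distance, axis_point)`` where ``distance`` is as in
    :func:`capsule_chain_distance` and ``axis_point`` is the closest point
    on the skeleton polyline.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    skeleton = np.asarray(skeleton, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(skeleton) == 1:
        d = np.linalg.norm(points - skeleton[0], axis=1) - radii[0]
        return d, np.tile(skeleton[0], (len(points), 1))
    best = np.full(len(points), np.inf)
    best_axis = np.zeros_like(points)
    a = skeleton[:-1]
    b = skeleton[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    for s in range(len(a)):
        if denom[s] == 0.0:
            t = np.zeros(len(points))
        else:
            t = np.clip((points - a[s]) @ ab[s] / denom[s], 0.0, 1.0)
        closest = a[s] + t[:, None] * ab[s]
        r = radii[s] + t * (radii[s + 1] - radii[s])
        d = np.linalg.norm(points - closest, axis=1) - r
        better = d < best
        best[better] = d[better]
        best_axis[better] = closest[better]
    return best, best_axis


def polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline, starting at 0."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])
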