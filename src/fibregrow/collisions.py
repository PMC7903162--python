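"""Exact mesh-collision detection.

The phantom's central meshing guarantee is *zero* intersecting triangle
pairs between any two fibre surfaces.  This module verifies it from first
principles: candidate triangle pairs are pruned with bounding spheres and
then tested with the Moller interval test (two plane-side rejections, then
overlap of the two intersection intervals on the common plane-plane line).
Exactly touching or coplanar-overlapping pairs count as intersecting only
beyond the supplied tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["tri_tri_intersections", "count_mesh_intersections", "phantom_collision_summary"]


def _odd_vertex(sign: np.ndarray) -> np.ndarray:
    """Index of the vertex alone on its side of the other plane."""
    odd = np.zeros(len(sign), dtype=int)
    odd[sign[:, 0] * sign[:, 1] > 0] = 2
    mask = (sign[:, 0] * sign[:, 1] <= 0) & (sign[:, 0] * sign[:, 2] > 0)
    odd[mask] = 1
    return odd


def _interval(proj: np.ndarray, dv: np.ndarray, odd: np.ndarray) -> np.ndarray:
    """Intersection interval of each triangle with the other's plane,
    parameterised along the common line projection."""
    m = len(proj)
    rows = np.arange(m)
    others = np.array([[1, 2], [0, 2], [0, 1]])[odd]
    p0 = proj[rows, odd]
    d0 = dv[rows, odd]
    out = np.empty((m, 2))
    for col in range(2):
        a = others[:, col]
        pa = proj[rows, a]
        da = dv[rows, a]
        denom = d0 - da
        safe = np.abs(denom) > 1e-300
        t = np.where(safe, p0 + (pa - p0) * np.where(safe, d0 / np.where(safe, denom, 1.0), 0.0), pa)
        out[:, col] = t
    out.sort(axis=1)
    return out


def _coplanar_overlap(t1, t2, n, eps) -> np.ndarray:
    """2D separating-axis test for coplanar triangle pairs."""
    m = len(t1)
    if m == 0:
        return np.zeros(0, dtype=bool)
    axis_drop = np.argmax(np.abs(n), axis=1)
    keep_cols = np.array([[1, 2], [0, 2], [0, 1]])[axis_drop]
    rows = np.arange(m)[:, None, None]
    a2 = t1[rows, np.arange(3)[None, :, None], keep_cols[:, None, :]]
    b2 = t2[rows, np.arange(3)[None, :, None], keep_cols[:, None, :]]
    overlap = np.ones(m, dtype=bool)
    for tri_a, tri_b in ((a2, b2), (b2, a2)):
        for e in range(3):
            edge = tri_a[:, (e + 1) % 3] - tri_a[:, e]
            axis = np.stack([-edge[:, 1], edge[:, 0]], axis=1)
            pa = np.einsum("mvk,mk->mv", tri_a, axis)
            pb = np.einsum("mvk,mk->mv", tri_b, axis)
            scale = np.linalg.norm(axis, axis=1) + 1e-300
            sep = (pb.min(1) > pa.max(1) - eps * scale) | (pa.min(1) > pb.max(1) - eps * scale)
            overlap &= ~sep
    return overlap


def tri_tri_intersections(tris_a: np.ndarray, tris_b: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Boolean intersection flag per triangle pair.

    ``tris_a``/``tris_b`` are (M, 3, 3) arrays of paired triangles.
    """
    tris_a = np.asarray(tris_a, dtype=float)
    tris_b = np.asarray(tris_b, dtype=float)
    m = len(tris_a)
    if m == 0:
        return np.zeros(0, dtype=bool)
    n2 = np.cross(tris_b[:, 1] - tris_b[:, 0], tris_b[:, 2] - tris_b[:, 0])
    d2 = -np.einsum("mk,mk->m", n2, tris_b[:, 0])
    dv = np.einsum("mk,mvk->mv", n2, tris_a) + d2[:, None]
    scale2 = np.linalg.norm(n2, axis=1, keepdims=True) + 1e-300
    dv = np.where(np.abs(dv) <= eps * scale2, 0.0, dv)

    n1 = np.cross(tris_a[:, 1] - tris_a[:, 0], tris_a[:, 2] - tris_a[:, 0])
    d1 = -np.einsum("mk,mk->m", n1, tris_a[:, 0])
    du = np.einsum("mk,mvk->mv", n1, tris_b) + d1[:, None]
    scale1 = np.linalg.norm(n1, axis=1, keepdims=True) + 1e-300
    du = np.where(np.abs(du) <= eps * scale1, 0.0, du)

    result = np.zeros(m, dtype=bool)
    same_side_a = (np.all(dv > 0, axis=1)) | (np.all(dv < 0, axis=1))
    same_side_b = (np.all(du > 0, axis=1)) | (np.all(du < 0, axis=1))
    candidates = ~(same_side_a | same_side_b)

    coplanar = candidates & np.all(dv == 0.0, axis=1)
    straddle = candidates & ~coplanar
    if np.any(coplanar):
        result[coplanar] = _coplanar_overlap(
            tris_a[coplanar], tris_b[coplanar], n2[coplanar], eps
        )
    if np.any(straddle):
        idx = np.nonzero(straddle)[0]
        line = np.cross(n1[idx], n2[idx])
        axis = np.argmax(np.abs(line), axis=1)
        pa = np.take_along_axis(tris_a[idx], axis[:, None, None], axis=2)[:, :, 0]
        pb = np.take_along_axis(tris_b[idx], axis[:, None, None], axis=2)[:, :, 0]
        sign_a = np.sign(dv[idx])
        sign_b = np.sign(du[idx])
        ia = _interval(pa, dv[idx], _odd_vertex(sign_a))
        ib = _interval(pb, du[idx], _odd_vertex(sign_b))
        lo = np.maximum(ia[:, 0], ib[:, 0])
        hi = np.minimum(ia[:, 1], ib[:, 1])
        result[idx] = hi - lo > eps
    return result


def count_mesh_intersections(mesh_a, mesh_b, eps: float = 1e-9) -> int:
    """Number of intersecting triangle pairs between two meshes."""
    # fast reject: separated bounding boxes
    if np.any(mesh_a.bounds[1] < mesh_b.bounds[0]) or np.any(mesh_b.bounds[1] < mesh_a.bounds[0]):
        return 0
    ta = mesh_a.triangles
    tb = mesh_b.triangles
    ca = ta.mean(axis=1)
    cb = tb.mean(axis=1)
    ra = np.linalg.norm(ta - ca[:, None, :], axis=2).max(axis=1)
    rb = np.linalg.norm(tb - cb[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(cb)
    rb_max = float(rb.max())
    pairs_a = []
    pairs_b = []
    for i, hits in enumerate(tree.query_ball_point(ca, ra + rb_max)):
        if hits:
            pairs_a.extend([i] * len(hits))
            pairs_b.extend(hits)
    if not pairs_a:
        return 0
    pa = np.asarray(pairs_a)
    pb = np.asarray(pairs_b)
    close = np.linalg.norm(ca[pa] - cb[pb], axis=1) <= ra[pa] + rb[pb]
    pa, pb = pa[close], pb[close]
    if len(pa) == 0:
        return 0
    total = 0
    chunk = 200_000
    for s in range(0, len(pa), chunk):
        flags = tri_tri_intersections(ta[pa[s : s + chunk]], tb[pb[s : s + chunk]], eps)
        total += int(flags.sum())
    return total


def phantom_collision_summary(meshes, eps: float = 1e-9) -> dict:
    """Exhaustive pairwise collision check over a list of meshes."""
    n = len(meshes)
    intersecting_pairs = 0
    intersecting_triangles = 0
    for i in range(n):
        for j in range(i + 1, n):
            c = count_mesh_intersections(meshes[i], meshes[j], eps)
            if c:
                intersecting_pairs += 1
                intersecting_triangles += c
    return {
        "mesh_pairs_checked": n * (n - 1) // 2,
        "intersecting_mesh_pairs": intersecting_pairs,
        "intersecting_triangle_pairs": intersecting_triangles,
    }
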