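"""Post-growth relaxation of skeleton point positions.

Growth happens on a discrete node cloud, so grown fibres can sit closer to
(or further from) their neighbours than ideal.  For every interior skeleton
point ``i`` the nearest ``n`` points on *other* fibres are found and the
point is moved by

    u_i = sum_j sgn(r_i + r_j - |p_i - p_j|) * (p_i - p_j)

— repelled by neighbours closer than the touching distance ``r_i + r_j``,
attracted to ones further away — with ``|u_i|`` clamped to ``0.2 r_i`` per
sweep.  Updates are synchronous (Jacobi) so the result does not depend on
point ordering.  Sweeps stop when the total-overlap metric
``sum max(0, r_i + r_j - |p_i - p_j|)`` stops improving; the best iterate
seen is returned, so the final overlap never exceeds the initial one.
Fibre endpoints (start/target contract) are never moved, and this step
never touches radii.

After relaxation the pipeline may call :func:`recover_radii`, which
re-expands each point's radius toward its target ``d0/2`` subject to
clearance from other fibres — this is what converts the regained space
into phantom density.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ._rng import rng_from
from .geometry import capsule_chain_closest, capsule_chain_distance

__all__ = [
    "interaction_sign",
    "update_vector",
    "global_optimise",
    "recover_radii",
    "resolve_contacts",
]

DEFAULT_NEIGHBOURS = 10
MAX_STEP_FRACTION = 0.2


def interaction_sign(r_i: float, r_j: float, distance: float) -> int:
    """+1 repulsive (overlapping), 0 touching, -1 attractive (apart)."""
    if r_i <= 0 or r_j <= 0:
        raise ValueError("radii must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return int(np.sign(r_i + r_j - distance))


def update_vector(p_i, r_i, neighbour_points, neighbour_radii, rng=None) -> np.ndarray:
    """Displacement of point i from its other-fibre neighbour set, clamped
    to ``0.2 r_i``.  Coincident neighbours contribute a tiny seeded jitter."""
    p_i = np.asarray(p_i, dtype=float)
    pj = np.atleast_2d(neighbour_points)
    rj = np.atleast_1d(neighbour_radii)
    if len(pj) == 0:
        raise ValueError("neighbour set must be non-empty")
    diff = p_i - pj
    dist = np.linalg.norm(diff, axis=1)
    coincident = dist < 1e-12
    if np.any(coincident):
        rng = rng_from(rng)
        jitter = rng.standard_normal((int(coincident.sum()), 3))
        jitter /= np.linalg.norm(jitter, axis=1, keepdims=True)
        diff[coincident] = jitter * (1e-3 * r_i)
        dist[coincident] = 1e-3 * r_i
    sign = np.sign(r_i + rj - dist)
    u = (sign[:, None] * diff).sum(axis=0)
    norm = float(np.linalg.norm(u))
    cap = MAX_STEP_FRACTION * r_i
    if norm > cap:
        u *= cap / norm
    return u


def _gather(phantom):
    """Flatten completed fibres into point/radius/fibre-id arrays with
    interior masks (endpoints stay fixed).

    The radii used by the interaction rule are the *target* radii d0/2:
    the desired spacing between two points is the distance at which both
    fibres could carry their full target diameter.
    """
    pts, rad, fid, interior = [], [], [], []
    for k, f in enumerate(phantom.completed):
        n = len(f.radii)
        pts.append(f.skeleton)
        rad.append(np.full(n, f.d0 / 2.0))
        fid.append(np.full(n, k))
        m = np.zeros(n, dtype=bool)
        if n > 2:
            m[1:-1] = True
        interior.append(m)
    return (
        np.vstack(pts),
        np.concatenate(rad),
        np.concatenate(fid),
        np.concatenate(interior),
    )


def _scatter(phantom, points):
    off = 0
    for f in phantom.completed:
        n = len(f.radii)
        f.skeleton = points[off : off + n].copy()
        off += n


def global_optimise(
    phantom,
    n: int = DEFAULT_NEIGHBOURS,
    max_iters: int = 200,
    tolerance: float = 1e-4,
    rng=None,
) -> list[float]:
    """Relax skeleton positions across the phantom; returns the per-sweep
    total-overlap trace.  Positions of the best sweep are kept."""
    if len(phantom.completed) < 2:
        raise ValueError("global optimisation needs at least 2 completed fibres")
    rng = rng_from(rng)
    points, radii, fid, interior = _gather(phantom)
    m = len(points)
    k_query = min(m, n + 24)

    def sweep_state(points):
        tree = cKDTree(points)
        dist, idx = tree.query(points, k=k_query)
        # drop self/same-fibre columns, keep first n other-fibre neighbours
        other = fid[idx] != fid[:, None]
        nn_idx = np.full((m, n), -1)
        nn_dist = np.full((m, n), np.inf)
        for i in range(m):
            cols = idx[i][other[i]][:n]
            nn_idx[i, : len(cols)] = cols
            nn_dist[i, : len(cols)] = dist[i][other[i]][:n]
        return nn_idx, nn_dist

    def overlap_metric(nn_idx, nn_dist):
        valid = nn_idx >= 0
        rj = np.where(valid, radii[np.maximum(nn_idx, 0)], 0.0)
        pen = np.maximum(0.0, radii[:, None] + rj - nn_dist)
        return float(pen[valid].sum())

    trace = []
    nn_idx, nn_dist = sweep_state(points)
    current = overlap_metric(nn_idx, nn_dist)
    trace.append(current)
    best = current
    best_points = points.copy()
    for _ in range(max_iters):
        new_points = points.copy()
        for i in np.nonzero(interior)[0]:
            cols = nn_idx[i][nn_idx[i] >= 0]
            if len(cols) == 0:
                continue
            new_points[i] = points[i] + update_vector(
                points[i], radii[i], points[cols], radii[cols], rng
            )
        points = new_points
        nn_idx, nn_dist = sweep_state(points)
        current = overlap_metric(nn_idx, nn_dist)
        trace.append(current)
        if current < best:
            if best - current < tolerance * max(best, 1e-12):
                best = current
                best_points = points.copy()
                break
            best = current
            best_points = points.copy()
        elif current >= best and len(trace) > 2 and current >= trace[-2]:
            break
        if current <= 1e-12:
            break
    _scatter(phantom, best_points)
    return trace


def resolve_contacts(
    phantom,
    clearance_fraction: float = 0.6,
    max_sweeps: int = 8,
) -> int:
    """Push skeleton points out of other fibres' capsules.

    Discrete growth, end-point snapping and the synchronous relaxation can
    each leave individual skeleton points marginally inside a neighbouring
    capsule (sub-node-scale depths).  Such contacts violate the
    no-point-inside-a-capsule contract and, if deep relative to the local
    radius, would let the later fibre's implicit surface pierce the
    earlier one during meshing.  Each *interior* point whose distance to
    another fibre's surface is below ``clearance_fraction`` of its own
    radius is moved radially away from that capsule's axis up to the
    margin (a skeleton passing within ~0.2 of its radius of another
    surface puts twice the isolevel of chain field on it and pierces the
    earlier mesh; 0.6 leaves headroom for marching-cubes interpolation
    error on both meshes).  Fixed endpoints are left to the meshing
    stage, which drops too-close end sources instead.
    Returns the number of points moved in the final sweep (0 on success).
    """
    completed = phantom.completed
    if len(completed) < 2:
        return 0
    moved = 0
    for _ in range(max_sweeps):
        moved = 0
        for f in completed:
            if len(f.radii) < 3:
                continue
            interior = slice(1, len(f.radii) - 1)
            pts = f.skeleton[interior]
            need = clearance_fraction * f.radii[interior]
            for g in completed:
                if g is f:
                    continue
                d, axis_pt = capsule_chain_closest(pts, g.skeleton, g.radii)
                bad = d < need
                if not np.any(bad):
                    continue
                away = pts[bad] - axis_pt[bad]
                norm = np.linalg.norm(away, axis=1, keepdims=True)
                # a point exactly on the axis has no outward direction;
                # nudge along the fibre-local normal proxy (x) instead
                degenerate = norm[:, 0] < 1e-12
                away[degenerate] = np.array([1.0, 0.0, 0.0])
                norm[degenerate] = 1.0
                shift = (need[bad] - d[bad])[:, None] * away / norm
                pts[bad] = pts[bad] + shift
                moved += int(bad.sum())
            f.skeleton[interior] = pts
        if moved == 0:
            break
    return moved


def recover_radii(phantom, sweeps: int = 2) -> None:
    """Re-expand realized radii toward each fibre's target ``d0/2``,
    limited by the clearance to every other fibre's surface.

    Expansion only: a point's radius never drops below its grown value
    (growth already guaranteed non-overlap at the node scale, and the
    phantom density is a voxel union, so residual sub-node-scale contact
    cannot inflate it).  The meshing stage resolves any remaining
    surface-level contact by deformation.
    """
    completed = phantom.completed
    if len(completed) < 2:
        for f in completed:
            f.radii = np.minimum(np.maximum(f.radii, 0.0), f.d0 / 2.0)
        return
    for _ in range(sweeps):
        for f in completed:
            limit = np.full(len(f.radii), f.d0 / 2.0)
            for g in completed:
                if g is f:
                    continue
                # distance from this fibre's skeleton points to g's surface
                # is exactly the largest radius each point could carry
                d = capsule_chain_distance(f.skeleton, g.skeleton, g.radii)
                np.minimum(limit, d, out=limit)
            f.radii = np.maximum(f.radii, np.minimum(limit, f.d0 / 2.0))
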