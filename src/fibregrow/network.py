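"""The growth network: Delaunay-connected node cloud with occupancy state.

Each node stores ``dc``, the maximum fibre diameter sustainable there
without intersecting an existing fibre.  We define ``dc = 2 * clearance``
where clearance is the shortest distance from the node to any existing
fibre surface, so a fibre centred on the node with diameter ``dc`` just
touches its nearest neighbour.  ``dc`` only ever decreases (min-rule);
``bc`` records which bundle set the current minimum.  Nodes engulfed by a
fibre are flagged occupied/inaccessible rather than deleted, keeping the
triangulation bookkeeping consistent.

Dynamic insertion (the contact-guidance analogue) adds nodes in a shell
around a freshly grown fibre.  Re-triangulating the full cloud after every
fibre is prohibitively slow for realistic node counts, so by default the
patch of space around the fibre is re-triangulated locally and spliced
into the global adjacency; nodes deep inside the patch get exact local
Delaunay neighbourhoods, nodes at the patch rim keep their old links as
well (a superset graph — harmless for pathfinding).  A full rebuild is
used automatically for small clouds and available on request.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from ._rng import rng_from
from .geometry import capsule_chain_distance, polyline_arclength

__all__ = ["GrowthNetwork", "build_network", "update_network", "add_dynamic_nodes"]

#: clearances beyond this (um) leave dc at the infinity sentinel; nodes
#: further than this from every fibre read as "no fibre nearby", which
#: bounds both the node-update cost and the reach of the bundle-affinity
#: (fasciculation) term
DEFAULT_MAX_CLEARANCE = 2.5

_FULL_REBUILD_LIMIT = 60_000


def _adjacency_from_delaunay(tri: Delaunay) -> list:
    indptr, indices = tri.vertex_neighbor_vertices
    return [indices[indptr[i] : indptr[i + 1]].copy() for i in range(len(tri.points))]


class GrowthNetwork:
    def __init__(self, points: np.ndarray, adjacency: list, region=None):
        self.points = np.asarray(points, dtype=float)
        self.adjacency = adjacency
        self.region = None if region is None else np.asarray(region, dtype=float)
        n = len(self.points)
        self.dc = np.full(n, np.inf)
        self.bc = np.full(n, -1, dtype=np.int64)
        self.occupied = np.zeros(n, dtype=bool)
        self._tree = cKDTree(self.points)
        self._edge_q90 = self._edge_length_quantile(0.9)

    # -- basic queries -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.points)

    @property
    def tree(self) -> cKDTree:
        return self._tree

    @property
    def completion_tolerance(self) -> float:
        """90th-percentile Delaunay edge length; the head 'reaches' a target
        when it comes within this distance of it."""
        return self._edge_q90

    def neighbors(self, i: int) -> np.ndarray:
        """Accessible neighbours of node i (empty when i itself is occupied)."""
        if self.occupied[i]:
            return np.empty(0, dtype=np.int64)
        adj = self.adjacency[i]
        return adj[~self.occupied[adj]]

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    def _edge_length_quantile(self, q: float, max_nodes: int = 2000) -> float:
        n = len(self.points)
        take = np.arange(n) if n <= max_nodes else np.linspace(0, n - 1, max_nodes).astype(int)
        lengths = []
        for i in take:
            adj = self.adjacency[i]
            if len(adj):
                lengths.append(np.linalg.norm(self.points[adj] - self.points[i], axis=1))
        if not lengths:
            return np.inf
        return float(np.quantile(np.concatenate(lengths), q))

    # -- snapshots ---------------------------------------------------------
    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "dc": self.dc,
                "bc": self.bc,
                "occupied": self.occupied,
            }
        )


def build_network(points: np.ndarray, region=None) -> GrowthNetwork:
    """Delaunay-triangulate a node cloud into a growth network."""
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValueError("need at least 4 points to triangulate in 3D")
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise ValueError(
            "Delaunay triangulation failed (points may be coplanar or degenerate): "
            f"{exc}"
        ) from exc
    return GrowthNetwork(points, _adjacency_from_delaunay(tri), region)


def _fibre_node_shortlist(net: GrowthNetwork, skeleton, radii, reach: float) -> np.ndarray:
    """Indices of nodes within `reach` of the fibre surface (conservative)."""
    skeleton = np.asarray(skeleton, dtype=float)
    radii = np.asarray(radii, dtype=float)
    mids = 0.5 * (skeleton[:-1] + skeleton[1:]) if len(skeleton) > 1 else skeleton
    half = (
        0.5 * np.linalg.norm(np.diff(skeleton, axis=0), axis=1)
        if len(skeleton) > 1
        else np.zeros(1)
    )
    rmax = float(radii.max())
    radius = float(half.max()) + rmax + reach
    lists = net.tree.query_ball_point(mids, radius)
    if len(mids) == 1:
        return np.asarray(lists[0] if len(lists) and isinstance(lists[0], list) else lists, dtype=np.int64)
    flat = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists if len(l)]) if len(lists) else np.empty(0, np.int64)
    return np.unique(flat)


def update_network(
    net: GrowthNetwork,
    fibre,
    max_clearance: float = DEFAULT_MAX_CLEARANCE,
) -> GrowthNetwork:
    """Fold one grown fibre into the node state (idempotent).

    For every node within reach: ``dc <- min(dc, 2 * clearance)``; nodes at
    non-positive clearance become occupied.  ``bc`` follows the minimum.
    """
    skeleton, radii = fibre.skeleton, fibre.radii
    if len(skeleton) < 2:
        raise ValueError("fibre must have at least 2 skeleton points")
    idx = _fibre_node_shortlist(net, skeleton, radii, max_clearance)
    if len(idx) == 0:
        return net
    dist = capsule_chain_distance(net.points[idx], skeleton, radii)
    within = dist <= max_clearance
    idx, dist = idx[within], dist[within]
    dc_new = 2.0 * np.maximum(dist, 0.0)
    improved = dc_new < net.dc[idx]
    net.dc[idx[improved]] = dc_new[improved]
    net.bc[idx[improved]] = fibre.bundle_index
    inside = idx[dist <= 0.0]
    net.occupied[inside] = True
    net.dc[inside] = 0.0
    net.bc[inside] = fibre.bundle_index
    return net


def _splice_local_patch(net, local_ids, new_points, path_points, r_inner):
    """Re-triangulate patch nodes + new nodes; splice adjacency globally."""
    n_old = len(net.points)
    n_new = len(new_points)
    all_pts = np.vstack([net.points[local_ids], new_points])
    global_ids = np.concatenate([local_ids, np.arange(n_old, n_old + n_new)])
    tri = Delaunay(all_pts)
    indptr, indices = tri.vertex_neighbor_vertices

    # nodes whose whole Delaunay neighbourhood is captured by the patch
    path_tree = cKDTree(path_points)
    d_path, _ = path_tree.query(all_pts)
    inner = d_path <= r_inner
    inner[len(local_ids):] = True  # new nodes always inner

    net.points = np.vstack([net.points, new_points])
    net.dc = np.concatenate([net.dc, np.full(n_new, np.inf)])
    net.bc = np.concatenate([net.bc, np.full(n_new, -1, dtype=np.int64)])
    net.occupied = np.concatenate([net.occupied, np.zeros(n_new, dtype=bool)])
    net.adjacency.extend([None] * n_new)

    # O(1) patch-membership lookup (np.isin would re-sort per node)
    in_patch = np.zeros(len(net.points), dtype=bool)
    in_patch[global_ids] = True

    mapped = global_ids[indices].astype(np.int64)
    per_node = np.split(mapped, indptr[1:-1])
    n_local = len(local_ids)
    for local_i in range(len(all_pts)):
        g = int(global_ids[local_i])
        links = per_node[local_i]
        if inner[local_i]:
            if local_i < n_local:
                # keep old links that leave the patch entirely
                old = net.adjacency[g]
                outside = old[~in_patch[old]]
                if len(outside):
                    links = np.concatenate([links, outside])
            net.adjacency[g] = links
        else:
            net.adjacency[g] = np.unique(np.concatenate([net.adjacency[g], links]))
    net._tree = cKDTree(net.points)
    return net


def add_dynamic_nodes(
    net: GrowthNetwork,
    fibre,
    n_added: int,
    seed=None,
    existing_fibres=None,
    rebuild: str = "auto",
    max_clearance: float = DEFAULT_MAX_CLEARANCE,
) -> GrowthNetwork:
    """Add ``n_added`` nodes in a shell around a grown fibre's path.

    Positions: uniform in arc length; radial offset in the plane normal to
    the local tangent, magnitude uniform in [1.05, 2.0] x local radius
    (always outside the fibre surface).  Nodes falling outside the padded
    region are dropped.  Node state is recomputed against
    ``existing_fibres`` (default: just the generating fibre).
    """
    if n_added < 0:
        raise ValueError("n_added must be non-negative")
    if n_added == 0:
        return net
    rng = rng_from(seed)
    skeleton = np.asarray(fibre.skeleton, dtype=float)
    radii = np.asarray(fibre.radii, dtype=float)
    arc = polyline_arclength(skeleton)
    total = arc[-1]
    if total <= 0:
        return net

    u = rng.random(n_added) * total
    seg = np.clip(np.searchsorted(arc, u, side="right") - 1, 0, len(arc) - 2)
    frac = (u - arc[seg]) / np.maximum(arc[seg + 1] - arc[seg], 1e-300)
    pos = skeleton[seg] + frac[:, None] * (skeleton[seg + 1] - skeleton[seg])
    r_local = radii[seg] + frac * (radii[seg + 1] - radii[seg])
    tangent = skeleton[seg + 1] - skeleton[seg]
    tangent /= np.maximum(np.linalg.norm(tangent, axis=1, keepdims=True), 1e-300)
    raw = rng.standard_normal((n_added, 3))
    raw -= (np.einsum("ij,ij->i", raw, tangent))[:, None] * tangent
    norm = np.linalg.norm(raw, axis=1, keepdims=True)
    # regenerate the measure-zero case of a vector parallel to the tangent
    bad = norm[:, 0] < 1e-12
    while np.any(bad):
        raw[bad] = rng.standard_normal((int(bad.sum()), 3))
        raw[bad] -= (np.einsum("ij,ij->i", raw[bad], tangent[bad]))[:, None] * tangent[bad]
        norm = np.linalg.norm(raw, axis=1, keepdims=True)
        bad = norm[:, 0] < 1e-12
    offset_dir = raw / norm
    magnitude = (1.05 + 0.95 * rng.random(n_added)) * r_local
    new_points = pos + magnitude[:, None] * offset_dir

    if net.region is not None:
        pad = getattr(net, "padding", 0.0)
        lo, hi = -pad, net.region + pad
        keep = np.all((new_points >= lo) & (new_points <= hi), axis=1)
        new_points = new_points[keep]
        seg = seg[keep]
        r_local = r_local[keep]
    if len(new_points) == 0:
        return net

    n_old = len(net.points)
    if rebuild == "auto":
        rebuild = "full" if n_old + len(new_points) <= _FULL_REBUILD_LIMIT else "local"
    if rebuild == "full":
        all_points = np.vstack([net.points, new_points])
        tri = Delaunay(all_points)
        adjacency = _adjacency_from_delaunay(tri)
        rebuilt = GrowthNetwork(all_points, adjacency, net.region)
        rebuilt.padding = getattr(net, "padding", 0.0)
        rebuilt.dc[:n_old] = net.dc
        rebuilt.bc[:n_old] = net.bc
        rebuilt.occupied[:n_old] = net.occupied
        net = rebuilt
    elif rebuild == "local":
        spacing = (np.prod(net.points.max(0) - net.points.min(0)) / n_old) ** (1.0 / 3.0)
        margin = 2.0 * spacing
        shell = 2.0 * float(radii.max())
        local_ids = _fibre_node_shortlist(net, skeleton, radii, shell + 2 * margin)
        # patch path samples for the inner/rim split
        n_samp = max(2, int(np.ceil(total / max(spacing, 1e-6))))
        t = np.linspace(0, total, n_samp)
        s_i = np.clip(np.searchsorted(arc, t, side="right") - 1, 0, len(arc) - 2)
        f_i = (t - arc[s_i]) / np.maximum(arc[s_i + 1] - arc[s_i], 1e-300)
        path_pts = skeleton[s_i] + f_i[:, None] * (skeleton[s_i + 1] - skeleton[s_i])
        r_inner = float(radii.max()) + shell + margin
        net = _splice_local_patch(net, local_ids, new_points, path_pts, r_inner)
    else:
        raise ValueError(f"unknown rebuild mode {rebuild!r}")

    # state of the new nodes against the phantom so far
    new_idx = np.arange(n_old, len(net.points))
    fibres = existing_fibres if existing_fibres is not None else [fibre]
    for fb in fibres:
        dist = capsule_chain_distance(net.points[new_idx], fb.skeleton, fb.radii)
        within = dist <= max_clearance
        dc_new = 2.0 * np.maximum(dist[within], 0.0)
        tgt = new_idx[within]
        improved = dc_new < net.dc[tgt]
        net.dc[tgt[improved]] = dc_new[improved]
        net.bc[tgt[improved]] = fb.bundle_index
        inside = new_idx[dist <= 0.0]
        net.occupied[inside] = True
        net.dc[inside] = 0.0
    return net
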