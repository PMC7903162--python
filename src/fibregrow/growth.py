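"""Fibre growth: greedy best-first pathfinding under biologically
motivated costs.

A fibre advances node-to-node along the growth network.  From head ``s``
each accessible Delaunay neighbour ``c`` is scored

    l = lt + f * ld

where the chemoattraction term

    lt = 1/2 * (|s-c| / (1 + |s-c|)) * (1 - cos(angle((c-s), (t-s))))

penalises long steps and steps away from the target ``t`` (0 <= lt < 1),
and the shrinkage term ``ld = max(0, (d0 - dc)/d0)`` penalises moving where
the sustainable diameter ``dc`` falls below the fibre's target diameter
``d0``.  With fasciculation, ``ld`` becomes bundle-conditional: when the
nearest bundle at ``c`` is the fibre's own, ``ld = |(d0 - dc)/d0|``, so
drifting away from the home bundle is penalised as well.

A stuck fibre collapses: the head retreats along its own skeleton by
``g0 + k * delta`` on the k-th attempt, blacklisting the abandoned nodes,
and regrows; after the attempts are exhausted the fibre is removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._rng import stage_rngs
from .config import FibreSeed, GrowthConfig, MechanismFlags
from .geometry import capsule_chain_distance, polyline_arclength
from .initialise import generate_growth_nodes, make_fibre_seeds
from .network import GrowthNetwork, add_dynamic_nodes, build_network, update_network

__all__ = [
    "Fibre",
    "Phantom",
    "cost_direction",
    "cost_diameter",
    "cost_diameter_fasciculation",
    "total_cost",
    "choose_next_node",
    "retreat_distance",
    "collapse",
    "grow_fibre",
    "grow_all",
    "STUCK",
]

logger = logging.getLogger(__name__)

STUCK = -1


# ---------------------------------------------------------------------------
# cost functions
# ---------------------------------------------------------------------------

def cost_direction(s, c, t, composition: str = "additive") -> float:
    """Chemoattraction cost lt.

    Both terms penalise what the mechanism is meant to penalise: the
    saturating step-length factor ``|s-c| / (1 + |s-c|)`` discourages very
    large steps and ``(1 - cos theta)`` discourages moving away from the
    target.  ``composition`` selects how they combine:

    * ``"additive"`` (default): ``lt = (step_factor + (1 - cos)) / 2``,
      range [0, 1.5).  Misalignment is penalised at every step length, so
      greedy growth drifts to the target in near-straight paths.
    * ``"product"``: ``lt = step_factor * (1 - cos) / 2``, range [0, 1).
      A literal product reading; it nullifies the angle penalty for short
      steps, which on a fine node cloud degenerates the committed greedy
      walk into a space-filling wander (kept for comparison only).
    """
    s = np.asarray(s, dtype=float)
    step = np.asarray(c, dtype=float) - s
    to_target = np.asarray(t, dtype=float) - s
    ns = np.linalg.norm(step)
    nt = np.linalg.norm(to_target)
    if ns == 0 or nt == 0:
        raise ValueError("zero-length step or target vector; lt undefined")
    cos_theta = np.clip(float(step @ to_target) / (ns * nt), -1.0, 1.0)
    step_factor = ns / (1.0 + ns)
    if composition == "product":
        return 0.5 * step_factor * (1.0 - cos_theta)
    if composition == "additive":
        return 0.5 * (step_factor + (1.0 - cos_theta))
    raise ValueError(f"unknown composition {composition!r}")


def cost_diameter(d0: float, dc: float) -> float:
    """Shrinkage cost ld = max(0, (d0 - dc)/d0)."""
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if not np.isfinite(dc):
        return 0.0
    return max(0.0, (d0 - dc) / d0)


def cost_diameter_fasciculation(d0: float, dc: float, bc, bf) -> float:
    """Bundle-conditional shrinkage cost.

    Same bundle nearest -> |(d0 - dc)/d0| (penalises both crowding and
    drifting away); different bundle or none nearby -> plain shrinkage.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if not np.isfinite(dc) or bc is None or bc < 0 or bc != bf:
        return cost_diameter(d0, dc)
    return abs((d0 - dc) / d0)


def total_cost(lt: float, ld: float, f: float) -> float:
    if f < 0:
        raise ValueError("cost weight f must be non-negative")
    return lt + f * ld


# ---------------------------------------------------------------------------
# fibre container
# ---------------------------------------------------------------------------

@dataclass
class Fibre:
    """Skeleton (points + radii) of one grown fibre."""

    seed: FibreSeed
    skeleton: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    radii: np.ndarray = field(default_factory=lambda: np.empty(0))
    node_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    status: str = "growing"  # growing | complete | removed
    n_collapses: int = 0

    @property
    def bundle_index(self) -> int:
        return self.seed.bundle_index

    @property
    def target_diameter(self) -> float:
        return self.seed.target_diameter

    @property
    def d0(self) -> float:
        return self.seed.target_diameter

    def segment_directions(self) -> np.ndarray:
        """Unit direction of each skeleton segment."""
        d = np.diff(self.skeleton, axis=0)
        n = np.linalg.norm(d, axis=1, keepdims=True)
        good = n[:, 0] > 0
        return d[good] / n[good]

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.skeleton, axis=0), axis=1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "point": np.arange(len(self.radii)),
                "x": self.skeleton[:, 0],
                "y": self.skeleton[:, 1],
                "z": self.skeleton[:, 2],
                "radius": self.radii,
                "node": self.node_indices,
            }
        )


class Phantom:
    """The grown fibre population plus growth bookkeeping."""

    def __init__(self, fibres, config=None, log=None):
        self.fibres = list(fibres)
        self.config = config
        self.log = log or []

    @property
    def completed(self):
        return [f for f in self.fibres if f.status == "complete"]

    @property
    def removed(self):
        return [f for f in self.fibres if f.status == "removed"]

    def __len__(self):
        return len(self.fibres)

    def clearance(self, points, exclude=None) -> np.ndarray:
        """Min signed distance from query points to any completed fibre surface."""
        points = np.atleast_2d(points)
        best = np.full(len(points), np.inf)
        for f in self.completed:
            if f is exclude or len(f.skeleton) < 2:
                continue
            np.minimum(best, capsule_chain_distance(points, f.skeleton, f.radii), out=best)
        return best


# ---------------------------------------------------------------------------
# pathfinding
# ---------------------------------------------------------------------------

def choose_next_node(
    net: GrowthNetwork,
    head: int,
    target: np.ndarray,
    d0: float,
    bundle: int,
    excluded,
    f: float = 0.2,
    fasciculation: bool = False,
    radius_floor_fraction: float = 0.1,
    composition: str = "additive",
) -> int:
    """Lowest-cost accessible neighbour of ``head``, or STUCK.

    ``excluded`` is the union of the fibre's own visited path and its
    collapse blacklist.  Ties break to the lowest node index.
    """
    cand = net.neighbors(head)
    if len(cand) == 0:
        return STUCK
    keep = [
        c
        for c in cand
        if c not in excluded and net.dc[c] >= radius_floor_fraction * d0
    ]
    if not keep:
        return STUCK
    keep = np.sort(np.asarray(keep, dtype=np.int64))
    s = net.points[head]
    best_cost = np.inf
    best = STUCK
    for c in keep:
        lt = cost_direction(s, net.points[c], target, composition)
        if fasciculation:
            ld = cost_diameter_fasciculation(d0, net.dc[c], int(net.bc[c]), bundle)
        else:
            ld = cost_diameter(d0, net.dc[c])
        l = total_cost(lt, ld, f)
        assert 0.0 <= lt < 1.5 and ld >= 0.0 and l >= 0.0
        if l < best_cost - 1e-15:
            best_cost = l
            best = int(c)
    return best


def retreat_distance(k: int, g0: float = 2.0, delta: float = 5.0) -> float:
    """Arc length of the k-th collapse retreat: g0 + k * delta."""
    if k < 0:
        raise ValueError("collapse attempt index must be non-negative")
    return g0 + k * delta


def collapse(fibre: Fibre, k: int, blacklist: set, g0: float = 2.0, delta: float = 5.0) -> Fibre:
    """Retreat the head by ``g0 + k*delta`` of arc length, blacklisting the
    abandoned suffix.  Retreat past the start clamps at the first point."""
    dist = retreat_distance(k, g0, delta)
    arc = polyline_arclength(fibre.skeleton)
    from_head = arc[-1] - arc
    # last index whose distance-from-head >= dist (i.e. retreat at least dist)
    keep_until = int(np.searchsorted(-from_head, -dist, side="left"))
    keep_until = max(0, min(keep_until, len(arc) - 1))
    if keep_until >= len(arc) - 1:
        keep_until = max(0, len(arc) - 2)
    for idx in fibre.node_indices[keep_until + 1 :]:
        if idx >= 0:
            blacklist.add(int(idx))
    fibre.skeleton = fibre.skeleton[: keep_until + 1]
    fibre.radii = fibre.radii[: keep_until + 1]
    fibre.node_indices = fibre.node_indices[: keep_until + 1]
    fibre.n_collapses += 1
    return fibre


def _target_face_normal(seed: FibreSeed, region) -> tuple[int, float] | None:
    """Axis and plane coordinate of the boundary face containing the target."""
    region = np.asarray(region, dtype=float)
    t = seed.target_point
    for axis in range(3):
        for bound in (0.0, region[axis]):
            if abs(t[axis] - bound) < 1e-6:
                return axis, bound
    return None


def grow_fibre(
    net: GrowthNetwork,
    seed: FibreSeed,
    config: GrowthConfig,
    mechanisms: MechanismFlags,
    phantom: Phantom | None = None,
    max_steps: int | None = None,
) -> Fibre:
    """Grow one fibre along the network; returns it complete or removed."""
    fibre = Fibre(seed)
    d0 = seed.target_diameter
    target = seed.target_point
    region = np.asarray(config.region_size, dtype=float)
    tol = net.completion_tolerance
    face = _target_face_normal(seed, region)
    floor = config.radius_floor_fraction

    start_radius = d0 / 2.0
    if phantom is not None and len(phantom.completed):
        clr = float(phantom.clearance(seed.start_point[None, :])[0])
        if clr <= floor * d0 / 2.0:
            fibre.status = "removed"
            return fibre
        start_radius = min(start_radius, clr)

    # head = nearest accessible node with workable clearance
    k = min(len(net), 32)
    _, nearest = net.tree.query(seed.start_point, k=k)
    nearest = np.atleast_1d(nearest)
    head = None
    for c in nearest:
        if not net.occupied[c] and net.dc[c] >= floor * d0:
            head = int(c)
            break
    if head is None:
        fibre.status = "removed"
        return fibre

    points = [seed.start_point.copy()]
    radii = [start_radius]
    nodes = [np.int64(-1)]

    def push(node):
        points.append(net.points[node].copy())
        radii.append(min(d0, net.dc[node]) / 2.0)
        nodes.append(np.int64(node))

    push(head)
    visited = {head}
    blacklist: set[int] = set()
    if max_steps is None:
        max_steps = max(500, int(40 * np.linalg.norm(target - seed.start_point) / max(tol, 1e-6)))

    attempts = 0
    steps = 0
    while steps < max_steps:
        steps += 1
        hpos = points[-1]
        # completion: within tolerance of the target, or past its face plane
        if np.linalg.norm(hpos - target) <= tol:
            break
        if face is not None:
            axis, bound = face
            inward = 1.0 if bound == 0.0 else -1.0
            if (hpos[axis] - bound) * inward <= 0.0 and len(points) > 2:
                break
        nxt = choose_next_node(
            net,
            head,
            target,
            d0,
            seed.bundle_index,
            visited | blacklist,
            f=config.cost_weight,
            fasciculation=mechanisms.fasciculation,
            radius_floor_fraction=floor,
            composition=config.direction_cost,
        )
        if nxt == STUCK:
            if mechanisms.collapse and attempts <= config.collapse_max_attempts:
                fibre.skeleton = np.asarray(points)
                fibre.radii = np.asarray(radii)
                fibre.node_indices = np.asarray(nodes)
                collapse(fibre, attempts, blacklist, config.collapse_initial, config.collapse_increment)
                attempts += 1
                points = [p for p in fibre.skeleton]
                radii = list(fibre.radii)
                nodes = list(fibre.node_indices)
                visited = {int(n) for n in nodes if n >= 0}
                if nodes[-1] >= 0:
                    head = int(nodes[-1])
                else:
                    # retreated all the way to the start: re-anchor on the
                    # nearest accessible node not yet ruled out
                    _, cand = net.tree.query(points[-1], k=min(len(net), 32))
                    head = None
                    for c in np.atleast_1d(cand):
                        c = int(c)
                        if (
                            not net.occupied[c]
                            and c not in blacklist
                            and net.dc[c] >= floor * d0
                        ):
                            head = c
                            break
                    if head is None:
                        fibre.status = "removed"
                        return fibre
                    visited.add(head)
                    push(head)
                continue
            fibre.status = "removed"
            fibre.skeleton = np.asarray(points)
            fibre.radii = np.asarray(radii)
            fibre.node_indices = np.asarray(nodes)
            return fibre
        head = nxt
        visited.add(head)
        push(head)
    else:
        fibre.status = "removed"
        fibre.skeleton = np.asarray(points)
        fibre.radii = np.asarray(radii)
        fibre.node_indices = np.asarray(nodes)
        return fibre

    # snap the final point to the target
    end_radius = radii[-1]
    if phantom is not None and len(phantom.completed):
        clr = float(phantom.clearance(target[None, :])[0])
        # same floor as the growth accessibility rule: tips taper to at
        # most 10% of the target diameter, never to a degenerate sliver
        end_radius = max(min(end_radius, clr), floor * d0 / 2.0)
    points.append(target.copy())
    radii.append(end_radius)
    nodes.append(np.int64(-1))
    fibre.skeleton = np.asarray(points)
    fibre.radii = np.asarray(radii)
    fibre.node_indices = np.asarray(nodes)
    fibre.status = "complete"
    return fibre


def grow_all(
    config: GrowthConfig,
    mechanisms: MechanismFlags | None = None,
    seeds: list[FibreSeed] | None = None,
    net: GrowthNetwork | None = None,
) -> Phantom:
    """Grow a whole phantom: seeds, network, sequential growth, updates.

    Fibres grow one-by-one in a seeded random order; each completed fibre
    updates the network state and (when enabled) triggers dynamic node
    insertion.  Global optimisation, when enabled, relaxes positions and
    recovers radii afterwards (see :mod:`fibregrow.optimise`).
    """
    if mechanisms is None:
        mechanisms = MechanismFlags.all()
    rngs = stage_rngs(config.master_seed)
    if seeds is None:
        seeds = make_fibre_seeds(config, rngs)
    if net is None:
        nodes = generate_growth_nodes(
            config.region_size, config.n_nodes, rngs["nodes"], config.node_padding
        )
        net = build_network(nodes, config.region_size)
        net.padding = config.node_padding

    order = rngs["growth_order"].permutation(len(seeds))
    phantom = Phantom([], config=config)
    log = phantom.log
    dyn_rng = rngs["dynamic"]
    for pos, si in enumerate(order):
        seed = seeds[si]
        fibre = grow_fibre(net, seed, config, mechanisms, phantom)
        phantom.fibres.append(fibre)
        log.append(
            {
                "order": pos,
                "seed_index": int(si),
                "bundle": seed.bundle_index,
                "status": fibre.status,
                "n_collapses": fibre.n_collapses,
                "n_points": len(fibre.radii),
            }
        )
        logger.info(
            "fibre %d/%d (%s) bundle=%d collapses=%d",
            pos + 1,
            len(seeds),
            fibre.status,
            seed.bundle_index,
            fibre.n_collapses,
        )
        if fibre.status != "complete":
            continue
        update_network(net, fibre)
        if mechanisms.dynamic_network and config.n_added > 0:
            add_dynamic_nodes(
                net,
                fibre,
                config.n_added,
                dyn_rng,
                existing_fibres=phantom.completed,
            )
    if not phantom.completed:
        import warnings

        warnings.warn("no fibre completed; phantom is empty", stacklevel=2)
    if mechanisms.global_optimisation and len(phantom.completed) >= 2:
        from .optimise import global_optimise, recover_radii, resolve_contacts

        global_optimise(phantom, rng=rngs["optimise"])
        recover_radii(phantom)
        # last: geometric consistency for the meshing guarantee (radius
        # recovery moves neighbouring surfaces, so it must precede this)
        resolve_contacts(phantom)
    elif len(phantom.completed) >= 2:
        # numerical cleanup only: discrete growth and end snapping can
        # leave points marginally inside a neighbour at sub-node scale
        from .optimise import resolve_contacts

        resolve_contacts(phantom)
    phantom.network = net
    return phantom
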