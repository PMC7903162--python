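"""Initial growth configuration: starting points, target points, node cloud.

Starting points come from 2D circle packing on each bundle's entry face;
each fibre is assigned a direction drawn from the bundle's orientation
distribution, and its target point is the exit of the ray ``start + s*dir``
through the growth-region boundary.  The growth-node cloud uniformly
samples the region padded by ``2 * mu_r`` on every side so that fibres
hugging a face still have candidate nodes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_from, stage_rngs
from .config import BundleSpec, FibreSeed, GrowthConfig, ParameterError
from .directions import sample_esag, sample_watson
from .packing import pack_circles_2d, sample_radii

__all__ = [
    "generate_growth_nodes",
    "make_fibre_seeds",
    "ray_box_exit",
    "seeds_to_dataframe",
]


def generate_growth_nodes(region, n: int, seed=None, padding: float = 0.0) -> np.ndarray:
    """Uniform pseudorandom node cloud over the (padded) growth region."""
    if n < 4:
        raise ParameterError("need at least 4 nodes to triangulate")
    region = np.asarray(region, dtype=float)
    rng = rng_from(seed)
    lo = -padding
    hi = region + padding
    return lo + rng.random((int(n), 3)) * (hi - lo)


def ray_box_exit(start: np.ndarray, direction: np.ndarray, region) -> np.ndarray:
    """Exit point of the ray ``start + s * direction`` (s > 0) from the box [0, L]."""
    region = np.asarray(region, dtype=float)
    direction = np.asarray(direction, dtype=float)
    s_exit = np.inf
    for axis in range(3):
        d = direction[axis]
        if abs(d) < 1e-15:
            continue
        for bound in (0.0, region[axis]):
            s = (bound - start[axis]) / d
            if s > 1e-12:
                s_exit = min(s_exit, s)
    if not np.isfinite(s_exit):
        raise ParameterError("ray does not exit the region")
    return start + s_exit * direction


def _bundle_directions(model, kappa, mu, gamma, mean_direction, n, rng):
    if model == "parallel":
        return np.tile(np.asarray(mean_direction, dtype=float), (n, 1))
    if model == "watson":
        return sample_watson(kappa, mean_direction, n, rng)
    if model == "esag":
        # esag_mu encodes concentration through its norm; re-aim it at the
        # bundle's mean direction so per-bundle overrides stay consistent
        conc = float(np.linalg.norm(mu))
        aimed = conc * np.asarray(mean_direction, dtype=float)
        return sample_esag(aimed, gamma, n, rng)
    raise ParameterError(f"unknown dispersion model {model!r}")


def make_fibre_seeds(config: GrowthConfig, rngs: dict | None = None) -> list[FibreSeed]:
    """One seed per packed circle per bundle.

    The target point is the ray/boundary exit; the target diameter is twice
    the packed radius.  Directions whose component into the region vanishes
    are resampled (axial Watson draws are simply flipped into the inward
    hemisphere first — axes are sign-invariant).
    """
    region = np.asarray(config.region_size, dtype=float)
    if rngs is None:
        rngs = stage_rngs(config.master_seed)
    pack_rng, dir_rng = rngs["packing"], rngs["directions"]

    seeds: list[FibreSeed] = []
    for bundle in config.bundles:
        axis = bundle.face_axis
        other = [a for a in range(3) if a != axis]
        face_size = region[other]
        rho = config.bundle_density(bundle)
        area = float(face_size[0] * face_size[1])
        n_est = int(np.ceil(rho * area / (np.pi * config.radius_mean**2) * 1.6)) + 24
        radii = sample_radii(config.radius_mean, config.radius_std, n_est, pack_rng)
        packed = pack_circles_2d(radii, face_size, rho, pack_rng)

        face_coord = 0.0 if bundle.face_origin_side else region[axis]
        inward = 1.0 if bundle.face_origin_side else -1.0
        model, kappa, mu, gamma = config.bundle_dispersion(bundle)

        starts = np.zeros((len(packed), 3))
        starts[:, other[0]] = packed.centres[:, 0]
        starts[:, other[1]] = packed.centres[:, 1]
        starts[:, axis] = face_coord

        directions = _bundle_directions(
            model, kappa, mu, gamma, bundle.mean_direction, len(packed), dir_rng
        )
        for i in range(len(packed)):
            d = directions[i]
            for _ in range(200):
                comp = d[axis] * inward
                if model in ("parallel", "watson") and comp < 0:
                    d = -d  # axial distributions: flip into the region
                    comp = -comp
                if comp > 1e-9:
                    break
                d = _bundle_directions(
                    model, kappa, mu, gamma, bundle.mean_direction, 1, dir_rng
                )[0]
            else:
                raise ParameterError("could not sample a direction entering the region")
            target = ray_box_exit(starts[i], d, region)
            seeds.append(
                FibreSeed(
                    start_point=starts[i],
                    target_point=target,
                    target_diameter=2.0 * packed.radii[i],
                    bundle_index=bundle.bundle_index,
                )
            )
    return seeds


def seeds_to_dataframe(seeds: list[FibreSeed]) -> pd.DataFrame:
    rows = [
        {
            "x": s.start_point[0],
            "y": s.start_point[1],
            "z": s.start_point[2],
            "target_x": s.target_point[0],
            "target_y": s.target_point[1],
            "target_z": s.target_point[2],
            "d0": s.target_diameter,
            "bundle": s.bundle_index,
        }
        for s in seeds
    ]
    return pd.DataFrame(rows)


def octant_uniformity_pvalue(points: np.ndarray, lo, hi) -> float:
    """Chi-square p-value that points fill the box [lo, hi]^3 uniformly."""
    points = np.asarray(points, dtype=float)
    mid = 0.5 * (np.asarray(lo, dtype=float) + np.asarray(hi, dtype=float))
    octant = ((points > mid) * np.array([1, 2, 4])).sum(axis=1)
    counts = np.bincount(octant, minlength=8)
    return float(stats.chisquare(counts).pvalue)
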