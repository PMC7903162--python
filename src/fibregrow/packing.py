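"""2D circle packing for fibre entry faces.

Starting points for one bundle are the centres of non-overlapping circles
packed on the bundle's entry face at the target areal density.  The packer
uses random sequential insertion followed by iterative pairwise-repulsion
relaxation: all circles needed to meet the target density are dropped in at
random, then overlapping pairs are repeatedly pushed apart (and clamped
inside the face).  When the relaxation stalls — no reduction of the worst
overlap over 200 sweeps — the most conflicted circle is removed and
relaxation continues, so the result is always an overlap-free packing at
the highest density reached.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from ._rng import rng_from
from .config import ParameterError

__all__ = ["sample_radii", "pack_circles_2d", "PackingResult"]

_OVERLAP_TOL = 1e-9


def sample_radii(mu_r: float, sigma_r: float, n: int, seed=None) -> np.ndarray:
    """Sample ``n`` fibre radii from a gamma distribution with the given moments.

    The gamma family (shape ``mu^2/sigma^2``, scale ``sigma^2/mu``) is the
    usual positive-support choice for axon-radius phantoms; ``sigma_r = 0``
    degenerates to the constant ``mu_r``.
    """
    if mu_r <= 0:
        raise ParameterError("mu_r must be positive")
    if sigma_r < 0:
        raise ParameterError("sigma_r must be non-negative")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if sigma_r == 0:
        return np.full(n, float(mu_r))
    rng = rng_from(seed)
    shape = (mu_r / sigma_r) ** 2
    scale = sigma_r**2 / mu_r
    r = rng.gamma(shape, scale, size=n)
    # guard against numerically zero radii in extreme tails
    return np.maximum(r, 1e-6 * mu_r)


class PackingResult:
    """Circle centres, radii and achieved areal density of one packed face."""

    def __init__(self, centres: np.ndarray, radii: np.ndarray, face_size):
        self.centres = np.asarray(centres, dtype=float).reshape(-1, 2)
        self.radii = np.asarray(radii, dtype=float).reshape(-1)
        self.face_size = np.asarray(face_size, dtype=float)

    @property
    def density(self) -> float:
        area = float(self.face_size[0] * self.face_size[1])
        return float(np.sum(np.pi * self.radii**2) / area)

    def __len__(self) -> int:
        return len(self.radii)


def _overlap_state(centres, radii):
    """Per-circle summed overlap, worst pair overlap, and the pair list."""
    per = np.zeros(len(radii))
    if len(radii) < 2:
        return per, 0.0, None
    tree = cKDTree(centres)
    pairs = tree.query_pairs(2.0 * float(radii.max()), output_type="ndarray")
    if len(pairs) == 0:
        return per, 0.0, pairs
    i, j = pairs[:, 0], pairs[:, 1]
    overlap = radii[i] + radii[j] - np.linalg.norm(centres[i] - centres[j], axis=1)
    overlap = np.maximum(overlap, 0.0)
    np.add.at(per, i, overlap)
    np.add.at(per, j, overlap)
    return per, float(overlap.max()), pairs


def _push_apart(centres, radii, pairs, lo, hi, rng):
    """One repulsion sweep: move each overlapping pair apart, clamp inside."""
    i, j = pairs[:, 0], pairs[:, 1]
    d = centres[i] - centres[j]
    dist = np.linalg.norm(d, axis=1)
    need = radii[i] + radii[j]
    mask = need - dist > _OVERLAP_TOL
    i, j, d, dist = i[mask], j[mask], d[mask], dist[mask]
    overlap = need[mask] - dist
    zero = dist < 1e-12
    if np.any(zero):
        d[zero] = rng.standard_normal((int(zero.sum()), 2))
        dist[zero] = np.linalg.norm(d[zero], axis=1)
    push = (0.55 * overlap / dist)[:, None] * d
    delta = np.zeros_like(centres)
    np.add.at(delta, i, push)
    np.add.at(delta, j, -push)
    return np.clip(centres + delta, lo, hi)


def pack_circles_2d(radii, face_size, rho_target: float, seed=None, max_sweeps: int = 30000) -> PackingResult:
    """Pack non-overlapping circles onto a rectangular face.

    Parameters
    ----------
    radii : candidate circle radii (um); circles are consumed largest-first
        until their summed area reaches ``rho_target`` of the face area.
    face_size : (2,) face dimensions in um.
    rho_target : target areal density in (0, 1].

    Returns a :class:`PackingResult`; a warning (not an error) is emitted
    when the target density could not be reached.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ParameterError("all radii must be positive")
    if not (0.0 < rho_target <= 1.0):
        raise ParameterError("rho_target must lie in (0, 1]")
    face = np.asarray(face_size, dtype=float)
    if np.any(face <= 2 * radii.min()):
        raise ParameterError("face too small for the smallest circle")
    rng = rng_from(seed)

    area = float(face[0] * face[1])
    # consume radii in sample order so the packed subset keeps the target
    # radius distribution (sorting by size would bias it upward)
    cum = np.cumsum(np.pi * radii**2) / area
    n = min(int(np.searchsorted(cum, rho_target) + 1), len(radii))
    radii = radii[:n].copy()
    centres = radii[:, None] + rng.random((n, 2)) * (face[None, :] - 2 * radii[:, None])

    def relax(centres, eff, budget, tol):
        """Relax at fixed radii until the worst pair overlap <= tol."""
        lo = eff[:, None] * np.ones((1, 2))
        hi = face[None, :] - eff[:, None]
        spent = 0
        while spent < budget:
            spent += 1
            _, worst, pairs = _overlap_state(centres, eff)
            if worst <= tol:
                return centres, worst, spent
            centres = _push_apart(centres, eff, pairs, lo, hi, rng)
        _, worst, _ = _overlap_state(centres, eff)
        return centres, worst, spent

    # event-driven inflation: resolve overlaps at the current radius scale
    # (to a loose working tolerance — the push converges geometrically)
    # before growing the radii further; settles toward a jammed packing
    loose = 1e-5 * float(radii.mean())
    sweep = 0
    scale = 0.5
    step = 0.02
    while scale < 1.0 and sweep < 2 * max_sweeps // 3:
        centres, worst, spent = relax(centres, radii * scale, 300, loose)
        sweep += spent
        step = min(0.03, step * 1.3) if spent < 60 else max(0.004, step * 0.5)
        scale = min(1.0, scale + step)
    # final phase at full radii and strict tolerance; drop the most
    # conflicted circle whenever the relaxation stalls far short of it
    while sweep < max_sweeps:
        centres, worst, spent = relax(centres, radii, 5000, _OVERLAP_TOL)
        sweep += spent
        if worst <= 1e-4 * float(radii.min()):
            break
        per, _, _ = _overlap_state(centres, radii)
        keep = np.ones(len(radii), dtype=bool)
        keep[int(np.argmax(per))] = False
        radii, centres = radii[keep], centres[keep]

    # clear any microscopic residual exactly by shrinking all radii by it;
    # the density cost is O(residual / r) ~ 1e-4 at most
    _, worst, _ = _overlap_state(centres, radii)
    if worst > 0:
        radii = radii * (1.0 - 1.000001 * worst / (2.0 * float(radii.min())))
        _, worst, _ = _overlap_state(centres, radii)
    while len(radii) > 1 and worst > _OVERLAP_TOL:
        per, _, _ = _overlap_state(centres, radii)
        keep = np.ones(len(radii), dtype=bool)
        keep[int(np.argmax(per))] = False
        radii, centres = radii[keep], centres[keep]
        _, worst, _ = _overlap_state(centres, radii)

    result = PackingResult(centres, radii, face)
    if result.density < rho_target - 1e-6 and n > len(result):
        warnings.warn(
            f"target density {rho_target:.2f} unreachable; achieved {result.density:.3f} "
            f"with {len(result)} circles",
            stacklevel=2,
        )
    return result
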