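"""Directional distributions used to disperse fibre target points.

Two families are provided:

* the (bipolar) Watson distribution — antipodally symmetric, isotropic
  dispersion about a mean axis with concentration ``kappa``; density on the
  sphere proportional to ``exp(kappa * (mu . x)^2)``;
* the elliptically symmetric angular Gaussian (ESAG) — anisotropic
  dispersion obtained by normalising a trivariate Gaussian ``N(mu, V)``
  whose covariance satisfies ``V mu = mu`` and ``det V = 1``, parameterised
  by a 2-vector ``gamma`` controlling the ellipticity in the plane normal
  to ``mu``; ``gamma = (0, 0)`` reduces to the isotropic angular Gaussian.

Watson sampling is exact rejection sampling of ``u = cos(theta)`` against a
uniform envelope (accept with probability ``exp(kappa (u^2 - 1))``); samples
are returned in the hemisphere of the mean axis.
"""

from __future__ import annotations

import numpy as np

from ._rng import rng_from

__all__ = ["sample_watson", "sample_esag", "rotate_frame", "watson_cos_cdf"]


def rotate_frame(vectors: np.ndarray, new_z: np.ndarray) -> np.ndarray:
    """Rotate vectors expressed with +z as the pole so the pole maps to new_z."""
    new_z = np.asarray(new_z, dtype=float)
    nz = new_z / np.linalg.norm(new_z)
    z = np.array([0.0, 0.0, 1.0])
    c = float(z @ nz)
    if c > 1.0 - 1e-12:
        return vectors
    if c < -1.0 + 1e-12:
        # antipodal pole: rotate pi about x
        return vectors * np.array([1.0, -1.0, -1.0])
    axis = np.cross(z, nz)
    axis /= np.linalg.norm(axis)
    s = np.sqrt(max(0.0, 1.0 - c * c))
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    R = np.eye(3) + s * K + (1.0 - c) * (K @ K)
    return vectors @ R.T


def sample_watson(kappa: float, mean_axis=(0.0, 0.0, 1.0), n: int = 1, seed=None) -> np.ndarray:
    """Draw ``n`` axial unit vectors from a bipolar Watson distribution.

    Returned vectors lie in the hemisphere of ``mean_axis`` (axial data are
    sign-invariant so one representative per axis is reported).
    """
    if kappa <= 0:
        raise ValueError("Watson concentration kappa must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_from(seed)
    out = np.empty(n)
    filled = 0
    # Exact rejection on w = 1 - cos(theta): the target density
    # f(w) ~ exp(kappa (w^2 - 2w)) on [0, 1] is dominated by exp(-kappa w)
    # (since kappa w (w - 1) <= 0), so propose w ~ Exp(kappa) truncated to
    # [0, 1] and accept with probability exp(kappa (w^2 - w)).  Acceptance
    # stays O(1) at every concentration.
    while filled < n:
        m = int(min(5e6, max(3 * (n - filled) + 64, 1024)))
        w = rng.exponential(1.0 / kappa, size=m)
        keep = w <= 1.0
        w = w[keep]
        accept = rng.random(len(w)) < np.exp(kappa * (w * w - w))
        got = 1.0 - w[accept]
        take = min(len(got), n - filled)
        out[filled : filled + take] = got[:take]
        filled += take
    phi = rng.random(n) * 2.0 * np.pi
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - out * out))
    vecs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), out])
    return rotate_frame(vecs, mean_axis)


def watson_cos_cdf(kappa: float, grid: int = 20001):
    """Numerical CDF of u = cos(theta) on [0, 1]; independent check target."""
    u = np.linspace(0.0, 1.0, grid)
    dens = np.exp(kappa * (u * u - 1.0))
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(u))])
    return u, cdf / cdf[-1]


def _esag_precision(mu: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Inverse covariance with V mu = mu and det V = 1."""
    mu = np.asarray(mu, dtype=float)
    norm = np.linalg.norm(mu)
    mu_hat = mu / norm
    # deterministic orthonormal frame normal to mu
    ref = np.array([0.0, 0.0, 1.0]) if abs(mu_hat[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    xi1 = np.cross(mu_hat, ref)
    xi1 /= np.linalg.norm(xi1)
    xi2 = np.cross(mu_hat, xi1)
    g1, g2 = float(gamma[0]), float(gamma[1])
    gnorm = np.hypot(g1, g2)
    o11 = np.outer(xi1, xi1)
    o22 = np.outer(xi2, xi2)
    o12 = np.outer(xi1, xi2) + np.outer(xi2, xi1)
    return (
        np.eye(3)
        + (np.sqrt(gnorm * gnorm + 1.0) - 1.0) * (o11 + o22)
        + g1 * (o11 - o22)
        + g2 * o12
    )


def sample_esag(mu, gamma=(0.0, 0.0), n: int = 1, seed=None) -> np.ndarray:
    """Draw ``n`` unit vectors from the ESAG(mu, gamma) distribution.

    ``mu`` is a 3-vector whose norm acts as the concentration; ``gamma``
    shapes the elliptical cross-section of the dispersion.
    """
    mu = np.asarray(mu, dtype=float)
    if np.linalg.norm(mu) == 0:
        raise ValueError("ESAG mean vector mu must be non-zero")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_from(seed)
    prec = _esag_precision(mu, np.asarray(gamma, dtype=float))
    cov = np.linalg.inv(prec)
    # symmetrise against round-off before Cholesky
    cov = 0.5 * (cov + cov.T)
    L = np.linalg.cholesky(cov)
    y = mu + rng.standard_normal((n, 3)) @ L.T
    norms = np.linalg.norm(y, axis=1)
    # a Gaussian draw at exactly the origin has measure zero; guard anyway
    bad = norms < 1e-300
    if np.any(bad):
        y[bad] = mu
        norms[bad] = np.linalg.norm(mu)
    return y / norms[:, None]
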