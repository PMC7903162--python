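"""Morphometry of meshed fibre phantoms.

Measurement procedures mirror the ones used on real electron-microscopy
reconstructions of white matter so that phantom and tissue numbers are
directly comparable:

* centre lines — each fibre mesh is rotated so its end-to-end vector lies
  along z and the area-weighted centroids of equidistant cross-sections
  are connected;
* diameter profiles — the mesh is cut perpendicular to every centre-line
  segment and each cross-section area A is converted to the equivalent
  circle diameter ``d = 2 sqrt(A / pi)``;
* orientation distributions — segment directions are binned (forwards and
  backwards, so the result is exactly antipodally symmetric) on a
  subdivided icosahedral sphere and normalised to steradian^-1;
* virtual histology — planar sections of the whole phantom rasterised to
  a labelled image, from which per-axon shape metrics (circularity,
  convexity, eccentricity, area ratio) are extracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import trimesh
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage import measure as skmeasure

from .geometry import capsule_chain_distance

__all__ = [
    "CentreLine",
    "OrientationHistogram",
    "OrientationStats",
    "extract_centreline",
    "diameter_profile",
    "orientation_histogram",
    "orientation_stats",
    "measure_density",
    "virtual_histology_slice",
    "slice_morphometrics",
]


# ---------------------------------------------------------------------------
# centre lines and diameters
# ---------------------------------------------------------------------------

@dataclass
class CentreLine:
    points: np.ndarray  # (n_slices, 3)
    source: int | None = None

    @property
    def directions(self) -> np.ndarray:
        d = np.diff(self.points, axis=0)
        n = np.linalg.norm(d, axis=1, keepdims=True)
        return d / np.maximum(n, 1e-300)


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """4x4 transform rotating v onto +z."""
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(v @ z)
    T = np.eye(4)
    if c > 1 - 1e-12:
        return T
    if c < -1 + 1e-12:
        T[:3, :3] = np.diag([1.0, -1.0, -1.0])
        return T
    axis = np.cross(v, z)
    axis /= np.linalg.norm(axis)
    s = np.sqrt(1 - c * c)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    T[:3, :3] = np.eye(3) + s * K + (1 - c) * (K @ K)
    return T


def _section_loops(mesh, origin, normal):
    """Closed 3D loops of a mesh/plane intersection ([] when plane misses)."""
    sec = mesh.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return []
    return [np.asarray(d) for d in sec.discrete]


def _plane_basis(normal: np.ndarray):
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def extract_centreline(mesh, n_slices: int = 100, ends=None, source=None) -> CentreLine:
    """Connect the area-weighted centroids of equidistant cross-sections.

    The mesh is first rotated so its end-to-end vector (skeleton endpoints
    when given, else the two most distant vertices) aligns with z; the
    centre line is rotated back to the original frame.  Empty slices are
    interpolated from their neighbours with a warning.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    if ends is None:
        verts = mesh.vertices
        lo = verts[np.argmin(verts @ verts.mean(0))]
        d = np.linalg.norm(verts - lo, axis=1)
        e0 = verts[np.argmax(d)]
        d2 = np.linalg.norm(verts - e0, axis=1)
        e1 = verts[np.argmax(d2)]
    else:
        e0, e1 = np.asarray(ends[0], dtype=float), np.asarray(ends[1], dtype=float)
    T = _rotation_to_z(e1 - e0)
    rot = mesh.copy()
    rot.apply_transform(T)
    zmin, zmax = rot.bounds[0][2], rot.bounds[1][2]
    span = zmax - zmin
    zs = np.linspace(zmin + 1e-4 * span, zmax - 1e-4 * span, n_slices)
    centres = np.full((n_slices, 3), np.nan)
    for i, z in enumerate(zs):
        loops = _section_loops(rot, [0, 0, z], [0, 0, 1])
        if not loops:
            continue
        areas, cents = [], []
        for loop in loops:
            poly = Polygon(loop[:, :2])
            if not poly.is_valid:
                poly = poly.buffer(0)
            if poly.is_empty:
                continue
            areas.append(poly.area)
            c = poly.centroid
            cents.append([c.x, c.y])
        if not areas:
            continue
        areas = np.asarray(areas)
        cxy = (np.asarray(cents) * areas[:, None]).sum(0) / areas.sum()
        centres[i] = [cxy[0], cxy[1], z]
    missing = np.isnan(centres[:, 0])
    if np.all(missing):
        raise ValueError("no slice intersected the mesh")
    if np.any(missing):
        warnings.warn(f"{int(missing.sum())} empty slices interpolated", stacklevel=2)
        ok = np.nonzero(~missing)[0]
        for col in range(3):
            centres[missing, col] = np.interp(np.nonzero(missing)[0], ok, centres[ok, col])
    # rotate back
    R = T[:3, :3]
    return CentreLine(points=centres @ R, source=source)


def skeleton_centreline(skeleton, radii, n_points: int = 100) -> np.ndarray:
    """Centre line of a fibre directly from its skeleton.

    Emulates the mesh-based procedure (area centroids of equidistant
    slices) without meshing: the skeleton is resampled uniformly in arc
    length and box-smoothed over one fibre diameter — the scale over which
    the implicit surface averages skeleton jitter — then resampled to
    ``n_points``.  Endpoints are preserved.
    """
    skeleton = np.asarray(skeleton, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(skeleton) < 2:
        raise ValueError("need at least 2 skeleton points")
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(skeleton, axis=0), axis=1))])
    total = arc[-1]
    if total <= 0:
        raise ValueError("degenerate zero-length skeleton")
    fine_n = max(4 * n_points, 64)
    t = np.linspace(0.0, total, fine_n)
    fine = np.column_stack([np.interp(t, arc, skeleton[:, k]) for k in range(3)])
    window = 2.0 * float(radii.mean())  # one diameter
    half = max(1, int(round(window / (t[1] - t[0]) / 2.0)))
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    pad = np.pad(fine, ((half, half), (0, 0)), mode="edge")
    smooth = np.column_stack(
        [np.convolve(pad[:, k], kernel, mode="valid") for k in range(3)]
    )
    smooth[0], smooth[-1] = fine[0], fine[-1]
    idx = np.linspace(0, fine_n - 1, n_points).round().astype(int)
    return smooth[idx]


def diameter_profile(mesh, centreline: CentreLine):
    """Equivalent diameter at every centre-line segment plus the per-fibre
    coefficient of variation ``std(d)/mean(d)``."""
    pts = centreline.points
    dirs = centreline.directions
    diam = []
    for i in range(len(dirs)):
        mid = 0.5 * (pts[i] + pts[i + 1])
        loops = _section_loops(mesh, mid, dirs[i])
        if not loops:
            warnings.warn(f"section {i} missed the mesh; skipped", stacklevel=2)
            diam.append(np.nan)
            continue
        u, v = _plane_basis(dirs[i])
        best_area, best_d2 = 0.0, np.inf
        for loop in loops:
            rel = loop - mid
            poly = Polygon(np.column_stack([rel @ u, rel @ v]))
            if not poly.is_valid:
                poly = poly.buffer(0)
            if poly.is_empty:
                continue
            c = np.array([poly.centroid.x, poly.centroid.y])
            d2 = float(c @ c)
            # take the component the centre line actually passes through
            if d2 < best_d2:
                best_d2 = d2
                best_area = poly.area
        diam.append(2.0 * np.sqrt(best_area / np.pi))
    diam = np.asarray(diam)
    good = diam[np.isfinite(diam)]
    cv = float(np.std(good) / np.mean(good)) if len(good) else np.nan
    return diam, cv


# ---------------------------------------------------------------------------
# orientation distribution
# ---------------------------------------------------------------------------

def _spherical_triangle_solid_angle(a, b, c) -> np.ndarray:
    """Van Oosterom & Strackee solid angle of unit-vector triangles."""
    num = np.einsum("ij,ij->i", a, np.cross(b, c))
    den = (
        1.0
        + np.einsum("ij,ij->i", a, b)
        + np.einsum("ij,ij->i", b, c)
        + np.einsum("ij,ij->i", a, c)
    )
    return np.abs(2.0 * np.arctan2(num, den))


class OrientationHistogram:
    """Counts of segment directions on a subdivided icosahedral sphere.

    Every direction is binned forwards and backwards, so
    ``density[face] == density[antipode[face]]`` exactly.  Densities are
    per-steradian and integrate to 1 over the sphere.
    """

    def __init__(self, subdivisions: int = 3):
        sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        self.sphere = sphere
        centres = sphere.triangles_center
        self.face_normals = centres / np.linalg.norm(centres, axis=1, keepdims=True)
        tri = sphere.triangles
        solid = _spherical_triangle_solid_angle(tri[:, 0], tri[:, 1], tri[:, 2])
        self._tree = cKDTree(self.face_normals)
        _, self.antipode = self._tree.query(-self.face_normals)
        # the icosphere is centrally symmetric; average away the round-off
        # difference between paired faces so antipodal densities are equal
        # exactly, not just to machine precision
        self.solid_angles = 0.5 * (solid + solid[self.antipode])
        self.counts = np.zeros(len(self.face_normals), dtype=np.int64)

    def add(self, directions: np.ndarray) -> None:
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        norms = np.linalg.norm(directions, axis=1)
        good = norms > 0
        if not np.all(good):
            warnings.warn("zero-length segments skipped", stacklevel=2)
        d = directions[good] / norms[good, None]
        _, faces = self._tree.query(d)
        np.add.at(self.counts, faces, 1)
        np.add.at(self.counts, self.antipode[faces], 1)

    @property
    def density(self) -> np.ndarray:
        """Per-face density in steradian^-1."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.solid_angles)
        return self.counts / (total * self.solid_angles)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "face": np.arange(len(self.counts)),
                "nx": self.face_normals[:, 0],
                "ny": self.face_normals[:, 1],
                "nz": self.face_normals[:, 2],
                "solid_angle": self.solid_angles,
                "count": self.counts,
                "density": self.density,
            }
        )


def orientation_histogram(directions, subdivisions: int = 3) -> OrientationHistogram:
    hist = OrientationHistogram(subdivisions=subdivisions)
    hist.add(directions)
    return hist


@dataclass
class OrientationStats:
    mu_theta: float  # degrees in [0, 90]
    sigma_theta: float  # degrees
    reference_axis: tuple = (0.0, 0.0, 1.0)


def orientation_stats(directions, reference_axis=(0.0, 0.0, 1.0)) -> OrientationStats:
    """Mean/std of the (axially folded) angle from the reference axis."""
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    axis = np.asarray(reference_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    norms = np.linalg.norm(directions, axis=1)
    d = directions[norms > 0] / norms[norms > 0, None]
    cos_t = np.abs(np.clip(d @ axis, -1.0, 1.0))
    theta = np.degrees(np.arccos(cos_t))
    return OrientationStats(
        mu_theta=float(theta.mean()),
        sigma_theta=float(theta.std()),
        reference_axis=tuple(axis),
    )


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def measure_density(objects, roi, voxel: float = 0.2) -> float:
    """Fibre volume fraction of the ROI box by voxel-centre occupancy.

    ``objects`` may be fibres (skeleton + radii; fast capsule test) or
    triangle meshes (point containment; intended for small fixtures).
    A voxel counts as occupied when its centre lies inside any fibre.
    """
    lo = np.asarray(roi[0], dtype=float)
    hi = np.asarray(roi[1], dtype=float)
    axes = [np.arange(lo[d] + voxel / 2.0, hi[d], voxel) for d in range(3)]
    shape = tuple(len(a) for a in axes)
    if np.prod(shape) == 0:
        raise ValueError("ROI too small for the voxel size")
    occupied = np.zeros(shape, dtype=bool)

    fibre_like = [o for o in objects if hasattr(o, "skeleton")]
    mesh_like = [o for o in objects if not hasattr(o, "skeleton")]
    if fibre_like and voxel > max(float(np.min(f.radii)) for f in fibre_like):
        warnings.warn("voxel larger than the smallest fibre radius", stacklevel=2)

    for f in fibre_like:
        skel = np.asarray(f.skeleton)
        rad = np.asarray(f.radii)
        for s in range(len(skel) - 1):
            a, b = skel[s], skel[s + 1]
            rmax = max(rad[s], rad[s + 1])
            blo = np.minimum(a, b) - rmax
            bhi = np.maximum(a, b) + rmax
            ilo = np.maximum(np.searchsorted(axes[0], blo[0]), 0), np.maximum(
                np.searchsorted(axes[1], blo[1]), 0
            ), np.maximum(np.searchsorted(axes[2], blo[2]), 0)
            ihi = (
                np.searchsorted(axes[0], bhi[0]),
                np.searchsorted(axes[1], bhi[1]),
                np.searchsorted(axes[2], bhi[2]),
            )
            if any(l >= h for l, h in zip(ilo, ihi)):
                continue
            gx, gy, gz = np.meshgrid(
                axes[0][ilo[0] : ihi[0]],
                axes[1][ilo[1] : ihi[1]],
                axes[2][ilo[2] : ihi[2]],
                indexing="ij",
            )
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            inside = (
                capsule_chain_distance(pts, skel[s : s + 2], rad[s : s + 2]) <= 0.0
            ).reshape(gx.shape)
            occupied[ilo[0] : ihi[0], ilo[1] : ihi[1], ilo[2] : ihi[2]] |= inside

    if mesh_like:
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        for mesh in mesh_like:
            box = (np.all(pts >= mesh.bounds[0] - voxel, axis=1)) & (
                np.all(pts <= mesh.bounds[1] + voxel, axis=1)
            )
            if not np.any(box):
                continue
            inside = np.zeros(len(pts), dtype=bool)
            inside[box] = mesh.contains(pts[box])
            occupied |= inside.reshape(shape)

    return float(occupied.mean())


# ---------------------------------------------------------------------------
# virtual histology
# ---------------------------------------------------------------------------

def virtual_histology_slice(
    meshes,
    plane_origin,
    plane_normal,
    resolution: float = 0.005,
    bounds=None,
):
    """Rasterise the phantom/plane intersection to a labelled image.

    Returns ``(labels, info)``: labels is a 2D int array (0 = background,
    k = axon from meshes[k-1]); info records the pixel size, the in-plane
    basis and each axon's shapely polygon.
    """
    origin = np.asarray(plane_origin, dtype=float)
    u, v = _plane_basis(plane_normal)
    polys = {}
    for k, mesh in enumerate(meshes):
        loops = _section_loops(mesh, origin, plane_normal)
        if not loops:
            continue
        parts = []
        for loop in loops:
            rel = loop - origin
            p = Polygon(np.column_stack([rel @ u, rel @ v]))
            if not p.is_valid:
                p = p.buffer(0)
            if not p.is_empty:
                parts.append(p)
        if parts:
            polys[k + 1] = shapely.unary_union(parts)
    if not polys:
        warnings.warn("plane does not intersect the phantom", stacklevel=2)
        return np.zeros((1, 1), dtype=np.int32), {
            "pixel_size": resolution,
            "basis": (u, v),
            "origin": origin,
            "polygons": {},
        }
    if bounds is None:
        all_b = np.array([p.bounds for p in polys.values()])
        bounds = (
            all_b[:, 0].min() - resolution,
            all_b[:, 1].min() - resolution,
            all_b[:, 2].max() + resolution,
            all_b[:, 3].max() + resolution,
        )
    x0, y0, x1, y1 = bounds
    nx = int(np.ceil((x1 - x0) / resolution))
    ny = int(np.ceil((y1 - y0) / resolution))
    labels = np.zeros((ny, nx), dtype=np.int32)
    xs = x0 + (np.arange(nx) + 0.5) * resolution
    ys = y0 + (np.arange(ny) + 0.5) * resolution
    for label, poly in polys.items():
        bx0, by0, bx1, by1 = poly.bounds
        ix = np.nonzero((xs >= bx0 - resolution) & (xs <= bx1 + resolution))[0]
        iy = np.nonzero((ys >= by0 - resolution) & (ys <= by1 + resolution))[0]
        if len(ix) == 0 or len(iy) == 0:
            continue
        gx, gy = np.meshgrid(xs[ix], ys[iy])
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        sub = labels[np.ix_(iy, ix)]
        sub[inside] = label
        labels[np.ix_(iy, ix)] = sub
    info = {
        "pixel_size": resolution,
        "basis": (u, v),
        "origin": origin,
        "polygons": polys,
    }
    return labels, info


def slice_morphometrics(labels: np.ndarray, pixel_size: float) -> pd.DataFrame:
    """Per-axon shape metrics from a labelled histology image.

    circularity = 4 pi A / P^2, convexity = A / A_hull, eccentricity from
    the fitted ellipse (image second moments), area_ratio = A / (pi
    r_max^2) with r_max the minimum-enclosing-circle radius.  Axons
    touching the image edge are excluded, as are single-pixel regions.
    The perimeter is the length of the traced sub-pixel contour simplified
    at one-pixel tolerance: a raw marching-squares contour overestimates a
    disc's perimeter by ~5% and the Crofton estimator underestimates a
    square's by ~5%; the simplified contour recovers both closed forms
    within 1%.
    """
    rows = []
    for prop in skmeasure.regionprops(labels):
        label = prop.label
        minr, minc, maxr, maxc = prop.bbox
        touches = (
            minr == 0 or minc == 0 or maxr == labels.shape[0] or maxc == labels.shape[1]
        )
        if prop.area <= 1:
            warnings.warn(f"axon {label}: single-pixel region excluded", stacklevel=2)
            continue
        area = float(prop.area) * pixel_size**2
        hull_area = float(prop.area_convex) * pixel_size**2
        mask = np.pad(prop.image, 1)
        contours = skmeasure.find_contours(mask.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        poly = Polygon(contour[:, ::-1] * pixel_size)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        perimeter = float(poly.simplify(pixel_size).length)
        if perimeter == 0:
            continue
        r_max = float(shapely.minimum_bounding_radius(poly))
        rows.append(
            {
                "axon": label,
                "area": area,
                "perimeter": perimeter,
                "circularity": 4.0 * np.pi * area / perimeter**2,
                "convexity": area / hull_area if hull_area > 0 else np.nan,
                "eccentricity": prop.eccentricity,
                "area_ratio": area / (np.pi * r_max**2) if r_max > 0 else np.nan,
                "touches_edge": bool(touches),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df[~df["touches_edge"]].reset_index(drop=True)
    return df
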