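"""Fiber morphometry: waviness, tilt, cross-sectional area, diameter, orientation.

All quantities are measured on skeletons and surface meshes in physical
micrometres.  Waviness (tortuosity ratio) is arc length over end-to-end
chord; tilt encodes the out-of-plane z excursion relative to the in-plane
extent; CSA is the area of the closed polygon where the plane normal to
the local skeleton tangent cuts the surface mesh, approximated by an
area-equivalent circle for the diameter.  Diameters above a threshold
(default 6 μm) are flagged as outliers — such points come almost entirely
from inaccurate normal vectors or unsmooth surface patches — and excluded
from summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .frames import Curve3D, compute_tangents
from .segmentation import BinaryMask

__all__ = [
    "SurfaceMesh",
    "FiberMorphometry",
    "waviness",
    "tilt",
    "mesh_from_mask",
    "cross_section",
    "measure_csa_series",
    "orientation_2d",
    "split_bimodal",
]

logger = logging.getLogger(__name__)

DIAMETER_OUTLIER_UM = 6.0


@dataclass
class SurfaceMesh:
    """Triangulated fiber surface, vertices in physical (x, y, z) μm."""

    vertices: np.ndarray
    faces: np.ndarray

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @property
    def is_watertight(self) -> bool:
        return self.to_trimesh().is_watertight

    def export(self, path: str) -> None:
        """Write OBJ or PLY, chosen by file extension."""
        self.to_trimesh().export(path)


@dataclass
class FiberMorphometry:
    """Per-fiber measurement record."""

    fiber_id: object = None
    waviness: float = np.nan           # dimensionless, >= 1
    tilt_deg: float = np.nan           # [0, 90]
    orientation_deg: float = np.nan    # [0, 180)
    csa_um2: np.ndarray = field(default=None)       # per skeleton point
    diameter_um: np.ndarray = field(default=None)
    outlier: np.ndarray = field(default=None)       # per-point flags
    arc_length_um: np.ndarray = field(default=None)

    @property
    def csa_mean_sd(self) -> tuple[float, float]:
        good = self.csa_um2[~self.outlier]
        return float(np.mean(good)), float(np.std(good, ddof=1))

    @property
    def diameter_mean_sd(self) -> tuple[float, float]:
        good = self.diameter_um[~self.outlier]
        return float(np.mean(good)), float(np.std(good, ddof=1))

    @property
    def outlier_fraction(self) -> float:
        return float(np.mean(self.outlier))


def waviness(curve: Curve3D) -> float:
    """Tortuosity ratio: skeleton arc length / end-to-end Euclidean distance.

    Equals 1 for a straight fiber; invariant to rigid motion and uniform
    scaling.  A closed loop (coincident endpoints) is unsupported.
    """
    chord = float(np.linalg.norm(curve.points[-1] - curve.points[0]))
    if chord <= 1e-9:
        raise ValueError("coincident endpoints: closed loops are unsupported")
    return curve.total_length / chord


def tilt(curve: Curve3D) -> float:
    """Tilt (latitude) angle in degrees, in [0, 90].

    The z-coordinate range of the skeleton (max z − min z) is divided by
    the Euclidean distance between the endpoints projected onto the XY
    plane, and the ratio converted to an angle via arctan.  A vertical
    fiber (zero XY endpoint distance) is reported as 90°.
    """
    z = curve.points[:, 2]
    dz = float(z.max() - z.min())
    dxy = float(np.linalg.norm(curve.points[-1, :2] - curve.points[0, :2]))
    if dxy <= 0:
        logger.warning("vertical fiber: zero XY endpoint distance; tilt = 90")
        return 90.0
    return float(np.degrees(np.arctan(dz / dxy)))


def mesh_from_mask(mask: BinaryMask | np.ndarray, spacing,
                   smoothing_iters: int = 10, presmooth_sigma: float = 0.5,
                   min_component_faces: int = 32) -> SurfaceMesh:
    """Marching-cubes surface of a 3D binary mask, in physical μm.

    The mask is optionally Gaussian-presmoothed, the 0.5-isosurface is
    extracted, small disconnected shells are deleted, and the surface is
    relaxed by Laplacian smoothing with volume-preserving correction.
    The mask is zero-padded by one voxel so surfaces at the stack border
    stay closed.
    """
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if not data.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    padded = np.pad(data.astype(float), 1)
    if presmooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, sigma=presmooth_sigma)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(spacing))
    # marching_cubes works on the (z, y, x) grid; shift off the pad and
    # report (x, y, z) physical coordinates
    verts = verts - spacing[None, :]
    verts = verts[:, ::-1]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        parts = [p for p in parts if len(p.faces) >= min_component_faces]
        mesh = trimesh.util.concatenate(parts) if len(parts) > 1 else parts[0]
    if smoothing_iters > 0:
        # Taubin's lambda/mu scheme: Laplacian relaxation with the
        # anti-shrink correction pass, so tube cross sections keep their area
        trimesh.smoothing.filter_taubin(mesh, iterations=int(smoothing_iters))
    return SurfaceMesh(vertices=np.asarray(mesh.vertices),
                       faces=np.asarray(mesh.faces))


def cross_section(mesh: SurfaceMesh | trimesh.Trimesh, point, normal,
                  search_radius: float | None = None):
    """Cut the mesh with the plane through ``point`` with normal ``normal``.

    All mesh triangles crossing the plane yield a segment soup that is
    assembled into closed loops; the loop whose centroid is nearest the
    query point is selected and its enclosed area computed by the planar
    shoelace formula.  A plane can cut one mesh several times (a wavy
    fiber, or several fibers in one mesh) — only the loop around the
    skeleton point is wanted.

    Returns ``(polygon, area)``: the ordered 2D loop in plane coordinates
    and its area in μm², or ``(None, None)`` when no closed loop lies
    within ``search_radius`` of the point.
    """
    tm = mesh.to_trimesh() if isinstance(mesh, SurfaceMesh) else mesh
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    sec = tm.section(plane_origin=point, plane_normal=normal)
    if sec is None:
        return None, None
    planar, to_3d = sec.to_2D()
    best = None
    for poly in planar.polygons_closed:
        if poly is None:
            continue
        c2 = np.array(poly.centroid.coords[0])
        c3 = trimesh.transformations.transform_points(
            [[c2[0], c2[1], 0.0]], to_3d)[0]
        d = np.linalg.norm(c3 - point)
        if best is None or d < best[0]:
            best = (d, poly)
    if best is None:
        return None, None
    d, poly = best
    if search_radius is not None and d > search_radius:
        return None, None
    loop = np.array(poly.exterior.coords)
    # shoelace area of the selected loop
    x, y = loop[:, 0], loop[:, 1]
    area = 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))
    return loop, float(area)


def measure_csa_series(mesh: SurfaceMesh, skeleton: Curve3D,
                       diameter_outlier_um: float = DIAMETER_OUTLIER_UM,
                       normal_smooth_sigma: float = 2.0,
                       fiber_id=None) -> FiberMorphometry:
    """CSA and equivalent-diameter series along a refined skeleton.

    At every skeleton point the surface mesh is cut by the plane normal to
    the local tangent (center differences on the — optionally Gaussian
    pre-smoothed — skeleton; inaccurate normals are the dominant outlier
    source).  Equivalent diameter is ``2 sqrt(area / π)``.  Points whose
    diameter exceeds ``diameter_outlier_um`` or where no closed loop is
    found are flagged and excluded from summary statistics.
    """
    pts = skeleton.points
    if normal_smooth_sigma > 0 and len(pts) > 4:
        sm = ndimage.gaussian_filter1d(pts, sigma=normal_smooth_sigma, axis=0,
                                       mode="nearest")
        sm[0], sm[-1] = pts[0], pts[-1]
        tangents = compute_tangents(Curve3D(sm))
    else:
        tangents = compute_tangents(skeleton)

    tm = SurfaceMesh(mesh.vertices, mesh.faces).to_trimesh() \
        if isinstance(mesh, SurfaceMesh) else mesh
    n = len(pts)
    csa = np.full(n, np.nan)
    diam = np.full(n, np.nan)
    flagged = np.ones(n, dtype=bool)
    running: list[float] = []
    for i in range(n):
        med = np.median(running) if running else None
        radius = 2.0 * med if med is not None else None
        try:
            _, area = cross_section(tm, pts[i], tangents[i],
                                    search_radius=radius)
        except Exception:      # numerically degenerate cut
            area = None
        if area is None or area <= 0:
            continue
        d = 2.0 * np.sqrt(area / np.pi)
        csa[i] = area
        diam[i] = d
        if d <= diameter_outlier_um:
            flagged[i] = False
            running.append(d)
    if flagged.all():
        raise ValueError("all skeleton points flagged as outliers")
    return FiberMorphometry(
        fiber_id=fiber_id,
        waviness=waviness(skeleton),
        tilt_deg=tilt(skeleton),
        csa_um2=csa,
        diameter_um=diam,
        outlier=flagged,
        arc_length_um=skeleton.arc_length.copy(),
    )


def orientation_2d(region) -> float:
    """Principal-axis orientation of a 2D region, degrees in [0, 180).

    ``region`` is either a 2D boolean mask (rows = y, columns = x) or an
    ``(N, 2)`` array of (x, y) points.  The angle of the principal axis of
    the second central moments, ``θ = ½·atan2(2 μ11, μ20 − μ02)``, is
    measured counterclockwise from the +x axis.  An isotropic region has
    no defined orientation and raises.
    """
    region = np.asarray(region)
    if region.ndim == 2 and region.dtype == bool:
        ys, xs = np.nonzero(region)
        pts = np.stack([xs.astype(float), ys.astype(float)], axis=1)
    else:
        pts = np.atleast_2d(region).astype(float)
    if len(pts) < 2:
        raise ValueError("orientation needs a region, not a single point")
    c = pts - pts.mean(axis=0)
    mu20 = np.mean(c[:, 0] ** 2)
    mu02 = np.mean(c[:, 1] ** 2)
    mu11 = np.mean(c[:, 0] * c[:, 1])
    if abs(mu20 - mu02) < 1e-12 and abs(mu11) < 1e-12:
        raise ValueError("isotropic region: orientation undefined")
    theta = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    return float(np.degrees(theta) % 180.0)


def _circular_mean_sd_180(angles_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean and SD of axial angles (period 180°)."""
    doubled = np.deg2rad(2.0 * np.asarray(angles_deg, dtype=float))
    C, S = np.mean(np.cos(doubled)), np.mean(np.sin(doubled))
    mean = np.rad2deg(np.arctan2(S, C)) / 2.0 % 180.0
    R = np.hypot(C, S)
    sd = np.rad2deg(np.sqrt(max(-2.0 * np.log(max(R, 1e-300)), 0.0))) / 2.0
    return float(mean), float(sd)


def _axial_distance(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def split_bimodal(angles_deg, min_separation_deg: float = 10.0,
                  n_iter: int = 100):
    """Split axial angles (period 180°) into two populations.

    Two-means clustering on the doubled-angle circle; each cluster's
    circular mean and SD are reported on the 0–180° scale.  Angles that
    wrap past 0° are assigned by circular distance, so a value recorded as
    −5° (i.e. 175°) joins the low-angle population when that is nearer on
    the circle.  If the two recovered peaks are closer than
    ``min_separation_deg`` — or all angles are identical — the sample is
    treated as unimodal and a single (mean, SD) group is returned with a
    warning.

    Returns a list of one or two ``(mean_deg, sd_deg, n)`` tuples, sorted
    by descending population size.
    """
    angles = np.asarray(angles_deg, dtype=float) % 180.0
    if angles.size < 2:
        raise ValueError("need at least 2 angles")
    if np.allclose(angles, angles[0]):
        logger.warning("all angles identical; returning a single cluster")
        m, s = _circular_mean_sd_180(angles)
        return [(m, s, int(angles.size))]
    # initialize the two centers at the extremes of the doubled-angle spread
    doubled = 2.0 * angles
    emb = np.stack([np.cos(np.deg2rad(doubled)), np.sin(np.deg2rad(doubled))], axis=1)
    i0 = 0
    i1 = int(np.argmax(np.linalg.norm(emb - emb[i0], axis=1)))
    i0 = int(np.argmax(np.linalg.norm(emb - emb[i1], axis=1)))
    centers = np.array([angles[i0], angles[i1]])
    assign = np.zeros(angles.size, dtype=int)
    for _ in range(n_iter):
        dists = np.stack([[_axial_distance(a, c) for c in centers]
                          for a in angles])
        new_assign = np.argmin(dists, axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for k in (0, 1):
            if np.any(assign == k):
                centers[k] = _circular_mean_sd_180(angles[assign == k])[0]
    groups = []
    for k in (0, 1):
        sel = angles[assign == k]
        if sel.size:
            m, s = _circular_mean_sd_180(sel)
            groups.append((m, s, int(sel.size)))
    if len(groups) == 2 and _axial_distance(groups[0][0], groups[1][0]) < min_separation_deg:
        logger.warning("peaks closer than %.1f deg; merging into one cluster",
                       min_separation_deg)
        m, s = _circular_mean_sd_180(angles)
        return [(m, s, int(angles.size))]
    groups.sort(key=lambda g: -g[2])
    return groups
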