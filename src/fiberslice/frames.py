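"""Consistent orthonormal frames along a centerline and curved planar reformation.

A cross-sectional plane is placed at every centerline point with the plane
normal equal to the local curve tangent.  The in-plane axes are propagated
along the curve so that the normal vector rotates about the tangent as
little as possible between consecutive points (a rotation-minimizing
frame): this removes the flips and undefined directions of the raw
Frenet–Serret normal at inflections and straight segments, and makes the
resliced stack's in-plane orientation consistent from slice to slice.

The resliced stack is a sequence of rigid plane transforms plus the
resampled intensity grid; every transform is stored so segmented points can
be mapped back into the original image space exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation, Slerp

from .volume_io import ImageVolume, physical_to_voxel

__all__ = [
    "Curve3D",
    "FrameField",
    "ReslicePlane",
    "ResliceStack",
    "compute_tangents",
    "rotation_about_axis",
    "align_plane_to_tangent",
    "propagate_consistent_frames",
    "build_plane_grid",
    "reslice_volume",
    "map_back",
    "flatten_cpr",
]

logger = logging.getLogger(__name__)

_POLE_TOL = 1e-12


@dataclass
class Curve3D:
    """Ordered sub-voxel 3D point sequence in physical ``(x, y, z)`` μm.

    Carries cumulative arc length per point.  Consecutive points must be
    distinct and there must be at least two of them.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if len(self.points) < 2:
            raise ValueError("a curve needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            idx = int(np.flatnonzero(seg == 0)[0])
            raise ValueError(f"consecutive points {idx} and {idx + 1} coincide")
        self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


@dataclass
class FrameField:
    """Per-point orthonormal {tangent, normal, binormal} triads.

    The plane normal is identified with the curve tangent; ``normals`` and
    ``binormals`` span the cross-sectional plane.  ``rotation_deg`` records
    the angle by which each point's reference axes were rotated about the
    tangent during the consistency pass.
    """

    tangents: np.ndarray
    normals: np.ndarray
    binormals: np.ndarray
    rotation_deg: np.ndarray

    def __len__(self) -> int:
        return len(self.tangents)


@dataclass
class ReslicePlane:
    """One oriented sampling plane: center, in-plane unit axes u, v, grid geometry.

    Grid dimensions are ``(2R+1) x (2C+1)``; the directional axis ``a1``
    runs along u from in-plane offset ``(0, -C)`` to ``(0, C)`` — it plays
    the role of the sweeping line in a traditional CPR.
    """

    center: np.ndarray
    u: np.ndarray
    v: np.ndarray
    half_extent_r: int
    half_extent_c: int
    sample_spacing: float

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    @property
    def a1(self) -> np.ndarray:
        """Sweeping-line vector, from grid point (0, -C) to (0, C)."""
        return 2 * self.half_extent_c * self.sample_spacing * self.u

    def transform(self) -> np.ndarray:
        """4x4 rigid transform mapping in-plane (u-offset, v-offset, s) μm to world."""
        F = np.eye(4)
        t = np.cross(self.u, self.v)
        F[:3, 0] = self.u
        F[:3, 1] = self.v
        F[:3, 2] = t
        F[:3, 3] = self.center
        return F


@dataclass
class ResliceStack:
    """Resampled intensity grid along the curve plus per-plane rigid transforms."""

    planes: list
    intensities: np.ndarray      # (n_slices, 2R+1, 2C+1)
    valid: np.ndarray            # same shape, False where samples fell outside
    source_spacing: tuple = field(default=None)

    def __post_init__(self) -> None:
        if len(self.planes) != self.intensities.shape[0]:
            raise ValueError("one plane per slice required")

    @property
    def n_slices(self) -> int:
        return len(self.planes)


def compute_tangents(curve: Curve3D) -> np.ndarray:
    """Unit tangent per curve point.

    Interior points use the center difference ``p[i+1] - p[i-1]``; endpoints
    use one-sided differences.  All tangents are normalized.
    """
    p = curve.points
    d = np.empty_like(p)
    d[0] = p[1] - p[0]
    d[-1] = p[-1] - p[-2]
    if len(p) > 2:
        d[1:-1] = p[2:] - p[:-2]
    norms = np.linalg.norm(d, axis=1)
    bad = np.flatnonzero(norms < _POLE_TOL)
    if bad.size:
        raise ValueError(
            f"degenerate geometry: zero tangent at point index {int(bad[0])}"
        )
    return d / norms[:, None]


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues' rotation formula: 3x3 rotation about ``axis`` by ``angle_deg``.

    Right-handed sense; the axis is normalized internally.
    """
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n < _POLE_TOL:
        raise ValueError("rotation axis must be nonzero")
    k = a / n
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)


def align_plane_to_tangent(tangent) -> tuple[np.ndarray, np.ndarray]:
    """Initial in-plane axes (u, v) for a plane whose normal is ``tangent``.

    The reference plane has normal ``[0, 0, 1]`` and u along +y (the a1
    direction); it is carried onto the tangent by two rotations, azimuth
    about z and altitude about the rotated y axis, i.e. the tangent's
    spherical angles.  ``v = tangent x u`` so that ``(u, v, tangent)`` is
    right-handed.  At the ±z poles the azimuth is taken as 0 (documented
    fallback); the construction is continuous elsewhere.
    """
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    azimuth = 0.0 if abs(t[0]) < _POLE_TOL and abs(t[1]) < _POLE_TOL \
        else np.arctan2(t[1], t[0])
    altitude = np.arcsin(np.clip(t[2], -1.0, 1.0))
    beta = np.pi / 2 - altitude
    # R = Rz(azimuth) @ Ry(beta) maps [0,0,1] onto the tangent.
    Ry = Rotation.from_euler("y", beta).as_matrix()
    Rz = Rotation.from_euler("z", azimuth).as_matrix()
    R = Rz @ Ry
    u = R @ np.array([0.0, 1.0, 0.0])
    v = np.cross(t, u)
    v /= np.linalg.norm(v)
    u = u / np.linalg.norm(u)
    return u, v


def _step_angle_deg(ref_u, ref_v, n, t) -> float:
    """Signed angle (deg) rotating ref_u about t onto n."""
    c = float(np.clip(np.dot(ref_u, n), -1.0, 1.0))
    s = float(np.dot(np.cross(ref_u, n), t))
    return float(np.rad2deg(np.arctan2(s, c)))


def propagate_consistent_frames(curve: Curve3D, tangents: np.ndarray) -> FrameField:
    """Rotation-minimizing frame propagation along the curve.

    The first frame comes from :func:`align_plane_to_tangent`.  At each
    subsequent point the previous normal is projected onto the plane
    orthogonal to the current tangent and renormalized — the closed-form
    angle maximizing ``dot(n_i, n_{i+1})`` over rotations about the local
    tangent.  If the projection degenerates (previous normal parallel to
    the current tangent) the point falls back to the azimuth/altitude
    construction and a warning is logged.
    """
    t = np.asarray(tangents, dtype=float)
    if len(t) != len(curve):
        raise ValueError("tangents must match curve length")
    n = np.empty_like(t)
    b = np.empty_like(t)
    rot = np.zeros(len(t))
    u0, v0 = align_plane_to_tangent(t[0])
    n[0], b[0] = u0, v0
    for i in range(1, len(t)):
        proj = n[i - 1] - np.dot(n[i - 1], t[i]) * t[i]
        norm = np.linalg.norm(proj)
        if norm < 1e-8:
            logger.warning(
                "frame propagation degenerate at point %d; "
                "falling back to azimuth/altitude axes", i,
            )
            n[i], b[i] = align_plane_to_tangent(t[i])
        else:
            n[i] = proj / norm
            b[i] = np.cross(t[i], n[i])
        ref_u, ref_v = align_plane_to_tangent(t[i])
        rot[i] = _step_angle_deg(ref_u, ref_v, n[i], t[i])
    return FrameField(tangents=t, normals=n, binormals=b, rotation_deg=rot)


def build_plane_grid(half_extent_r: int, half_extent_c: int,
                     sample_spacing: float) -> np.ndarray:
    """Template lattice of in-plane offsets, shape ``(2R+1, 2C+1, 2)``.

    ``grid[i, j] = (u_offset, v_offset)`` in μm with the row index i running
    over v-offsets ``[-R, R]`` and the column index j over u-offsets
    ``[-C, C]``; the center element is exactly ``(0, 0)``.  The a1 template
    spans the j axis at i = 0, length ``2 * C * sample_spacing``.
    """
    R, C = int(half_extent_r), int(half_extent_c)
    if R < 1 or C < 1:
        raise ValueError("half extents must be >= 1")
    if sample_spacing <= 0:
        raise ValueError("sample spacing must be positive")
    iv = np.arange(-R, R + 1) * float(sample_spacing)
    ju = np.arange(-C, C + 1) * float(sample_spacing)
    grid = np.empty((2 * R + 1, 2 * C + 1, 2))
    grid[..., 0] = ju[None, :]   # u offsets along columns (a1 direction)
    grid[..., 1] = iv[:, None]   # v offsets along rows
    return grid


def reslice_volume(volume: ImageVolume, curve: Curve3D, frames: FrameField,
                   grid_template: np.ndarray, interpolation: str = "trilinear",
                   fill_value: float = 0.0) -> ResliceStack:
    """Resample the volume on a cross-sectional plane at every curve point.

    Slice i samples ``center_i + u_off * n_i + v_off * b_i`` for every
    template offset.  Trilinear (order 1) or cubic spline (order 3)
    interpolation; samples outside the volume are filled with
    ``fill_value`` and flagged invalid.
    """
    orders = {"trilinear": 1, "spline": 3}
    if interpolation not in orders:
        raise ValueError(f"unsupported interpolation {interpolation!r}")
    order = orders[interpolation]
    if len(frames) != len(curve):
        raise ValueError("frames must match curve length")

    R = (grid_template.shape[0] - 1) // 2
    C = (grid_template.shape[1] - 1) // 2
    spacing_inplane = float(grid_template[0, 1, 0] - grid_template[0, 0, 0])

    planes = []
    n_slices = len(curve)
    out = np.empty((n_slices,) + grid_template.shape[:2], dtype=float)
    valid = np.empty_like(out, dtype=bool)
    shape = np.array(volume.shape, dtype=float)
    offs = grid_template.reshape(-1, 2)

    vol = np.asarray(volume.intensities, dtype=float)
    if order == 3:  # prefilter once, sample with prefilter=False per slice
        vol_coeff = ndimage.spline_filter(vol, order=3)
    for i in range(n_slices):
        c = curve.points[i]
        u, v = frames.normals[i], frames.binormals[i]
        pts = c[None, :] + offs[:, 0:1] * u[None, :] + offs[:, 1:2] * v[None, :]
        zyx = physical_to_voxel(pts, volume)
        inside = np.all((zyx >= 0) & (zyx <= shape - 1), axis=1)
        if order == 1:
            vals = ndimage.map_coordinates(vol, zyx.T, order=1, mode="nearest")
        else:
            vals = ndimage.map_coordinates(vol_coeff, zyx.T, order=3,
                                           prefilter=False, mode="nearest")
        vals = np.where(inside, vals, fill_value)
        out[i] = vals.reshape(grid_template.shape[:2])
        valid[i] = inside.reshape(grid_template.shape[:2])
        planes.append(ReslicePlane(center=c.copy(), u=u.copy(), v=v.copy(),
                                   half_extent_r=R, half_extent_c=C,
                                   sample_spacing=spacing_inplane))
    return ResliceStack(planes=planes, intensities=out, valid=valid,
                        source_spacing=volume.spacing)


def map_back(points, stack: ResliceStack) -> np.ndarray:
    """Map reslice-space points back to original physical space.

    ``points`` rows are ``(slice_index, u_offset_um, v_offset_um)``; a
    fractional slice index interpolates between the two neighboring plane
    transforms (spherical-linear on the rotation, linear on the center).
    Composing with the forward sampling map is the identity: the grid
    center of slice i maps to curve point i.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    s = pts[:, 0]
    if np.any(s < 0) or np.any(s > stack.n_slices - 1):
        raise IndexError("slice index out of range")
    out = np.empty((len(pts), 3))
    for k, (si, a, b) in enumerate(pts):
        i0 = int(np.floor(si))
        frac = si - i0
        p0 = stack.planes[i0]
        if frac < 1e-12:
            center, u, v = p0.center, p0.u, p0.v
        else:
            p1 = stack.planes[i0 + 1]
            R0 = p0.transform()[:3, :3]
            R1 = p1.transform()[:3, :3]
            rots = Rotation.from_matrix(np.stack([R0, R1]))
            R = Slerp([0.0, 1.0], rots)(frac).as_matrix()
            center = (1 - frac) * p0.center + frac * p1.center
            u, v = R[:, 0], R[:, 1]
        out[k] = center + a * u + b * v
    return out


def flatten_cpr(stack: ResliceStack) -> np.ndarray:
    """Flattened longitudinal CPR image.

    One row per slice: the intensity profile along that slice's a1 sweeping
    line (the grid row at zero v-offset).  Height equals the number of
    curve points, width ``2C + 1``.
    """
    if stack.n_slices == 0:
        raise ValueError("empty stack")
    R = stack.planes[0].half_extent_r
    return stack.intensities[:, R, :].copy()
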