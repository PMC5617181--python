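"""Synthetic fiber phantoms with analytic ground truth.

Phantoms emulate the relevant properties of second-harmonic-generation
microscopy stacks of collagen fibers: bright tortuous tubes of roughly
1–3 μm diameter on a dark background, blurred by the optical point-spread
function, with additive detector noise, occasional low-intensity gaps, and
(optionally) spurious side branches.  Geometry defaults follow the scales
the measurement pipeline targets: radius ≈ 1.3 μm, waviness ≈ 1.37, tilt
≈ 5°, sampled at 0.25 μm.  Ground-truth parameters are computed from the
continuous centerline by quadrature, so they do not depend on the raster
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, ndimage, optimize
from scipy.spatial import cKDTree

from .frames import Curve3D
from .morphometry import orientation_2d, tilt as tilt_of_curve, waviness as waviness_of_curve
from .segmentation import BinaryMask
from .volume_io import ImageVolume

__all__ = [
    "FiberPhantomSpec",
    "PhantomTruth",
    "amplitude_for_waviness",
    "make_phantom",
    "make_branching_mask",
    "preset",
]

_FINE_STEP_UM = 0.02   # centerline quadrature step


@dataclass
class FiberPhantomSpec:
    """Declarative description of one phantom fiber.

    ``kind`` selects the centerline generator: ``straight``, ``sinusoidal``
    (amplitude/wavelength in μm), ``helical`` (amplitude = helix radius,
    wavelength = pitch) or ``piecewise`` (explicit control points).
    ``tilt_deg`` sets the out-of-plane inclination, ``orientation_deg`` the
    in-plane direction from +x.  ``radius_um`` may be a constant or a
    callable of arc length.  ``noise_sigma`` is additive Gaussian noise on
    the intensity scale set by ``contrast``; ``gaps`` is a list of
    ``(arc_start_um, arc_length_um)`` intervals where the fiber signal is
    suppressed.  The seed is fixed per instance: equal specs render
    bit-identical volumes.
    """

    kind: str = "sinusoidal"
    length_um: float = 25.0
    amplitude_um: float = 2.0
    wavelength_um: float = 12.0
    tilt_deg: float = 5.0
    orientation_deg: float = 20.0
    radius_um: object = 1.3
    contrast: float = 200.0
    blur_sigma_um: float = 0.25
    noise_sigma: float = 0.0
    gaps: list = field(default_factory=list)
    control_points: np.ndarray | None = None
    start_um: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_value(0.0) <= 0:
            raise ValueError("radius must be positive")
        if self.kind in ("sinusoidal", "helical") and self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive for periodic fibers")

    def radius_value(self, s) -> np.ndarray:
        return (self.radius_um(s) if callable(self.radius_um)
                else np.broadcast_to(float(self.radius_um), np.shape(s)).astype(float)
                if np.ndim(s) else float(self.radius_um))

    # -- continuous centerline -------------------------------------------
    def centerline(self, s: np.ndarray) -> np.ndarray:
        """Evaluate the continuous centerline at arc-like parameter ``s``."""
        s = np.asarray(s, dtype=float)
        th = np.deg2rad(self.orientation_deg)
        ti = np.deg2rad(self.tilt_deg)
        e1 = np.array([np.cos(th) * np.cos(ti), np.sin(th) * np.cos(ti), np.sin(ti)])
        e2 = np.array([-np.sin(th), np.cos(th), 0.0])
        e3 = np.cross(e1, e2)
        if self.kind == "straight":
            pts = s[:, None] * e1[None, :]
        elif self.kind == "sinusoidal":
            wob = self.amplitude_um * np.sin(2 * np.pi * s / self.wavelength_um)
            pts = s[:, None] * e1[None, :] + wob[:, None] * e2[None, :]
        elif self.kind == "helical":
            ph = 2 * np.pi * s / self.wavelength_um
            pts = (s[:, None] * e1[None, :]
                   + self.amplitude_um * np.cos(ph)[:, None] * e2[None, :]
                   + self.amplitude_um * np.sin(ph)[:, None] * e3[None, :])
        elif self.kind == "piecewise":
            if self.control_points is None:
                raise ValueError("piecewise fibers need control_points")
            cp = np.asarray(self.control_points, dtype=float)
            seg = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(cp, axis=0), axis=1))])
            u = s / s[-1] * seg[-1] if s[-1] > 0 else s
            pts = np.stack([np.interp(u, seg, cp[:, k]) for k in range(3)], axis=1)
        else:
            raise ValueError(f"unknown centerline kind {self.kind!r}")
        return pts


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a rendered phantom."""

    centerline: Curve3D
    waviness: float
    tilt_deg: float
    orientation_deg: float
    radius_um: np.ndarray
    mask: BinaryMask


def amplitude_for_waviness(target_w: float, wavelength_um: float) -> float:
    """Sinusoid amplitude giving a prescribed waviness over whole periods.

    For ``y = A sin(2πx/λ)`` the tortuosity over one period is
    ``(1/2π) ∫ sqrt(1 + u² cos² v) dv`` with ``u = 2πA/λ``; solved for A by
    bracketing.
    """
    if target_w < 1:
        raise ValueError("waviness cannot be below 1")
    if target_w == 1:
        return 0.0

    def w_of_u(u):
        val, _ = integrate.quad(lambda v: np.sqrt(1 + (u * np.cos(v)) ** 2),
                                0, 2 * np.pi)
        return val / (2 * np.pi)

    u = optimize.brentq(lambda u: w_of_u(u) - target_w, 1e-9, 50.0)
    return u * wavelength_um / (2 * np.pi)


def _fine_samples(spec: FiberPhantomSpec) -> np.ndarray:
    n = max(int(np.ceil(spec.length_um / _FINE_STEP_UM)), 64)
    return spec.centerline(np.linspace(0.0, spec.length_um, n + 1))


def _analytic_truth(spec: FiberPhantomSpec, centerline_pts: np.ndarray,
                    mask: BinaryMask) -> PhantomTruth:
    curve = Curve3D(centerline_pts)
    s = curve.arc_length
    w = waviness_of_curve(curve)
    t = tilt_of_curve(curve)
    if spec.kind == "straight":
        theta = spec.orientation_deg % 180.0
    else:
        theta = orientation_2d(centerline_pts[:, :2])
    return PhantomTruth(centerline=curve, waviness=w, tilt_deg=t,
                        orientation_deg=theta,
                        radius_um=np.atleast_1d(spec.radius_value(s)),
                        mask=mask)


def _render_tube_mask(centerline_pts: np.ndarray, radius_at: np.ndarray,
                      shape, spacing) -> np.ndarray:
    """Rasterize dist(voxel center, centerline) <= radius on the (z,y,x) grid."""
    sz, sy, sx = spacing
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(np.arange(nz) * sz, np.arange(ny) * sy,
                             np.arange(nx) * sx, indexing="ij")
    vox = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    tree = cKDTree(centerline_pts)
    rmax = float(np.max(radius_at))
    dist, idx = tree.query(vox, distance_upper_bound=rmax + 1e-9)
    hit = np.isfinite(dist)
    inside = np.zeros(len(vox), dtype=bool)
    inside[hit] = dist[hit] <= radius_at[np.clip(idx[hit], 0, len(radius_at) - 1)]
    return inside.reshape(shape)


def _place_centerline(spec: FiberPhantomSpec, pts: np.ndarray, shape, spacing):
    """Translate the centerline into the volume; error if it cannot fit."""
    sz, sy, sx = spacing
    extent = np.array([(shape[2] - 1) * sx, (shape[1] - 1) * sy,
                       (shape[0] - 1) * sz])
    rmax = float(np.max(np.atleast_1d(
        spec.radius_value(np.linspace(0, spec.length_um, 32)))))
    margin = 2.0 * rmax
    if spec.start_um is not None:
        pts = pts + np.asarray(spec.start_um, dtype=float)
    else:
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        pts = pts + (extent - (hi - lo)) / 2.0 - lo    # center in the volume
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    if np.any(lo < margin) or np.any(hi > extent - margin):
        raise ValueError(
            f"fiber exits volume: centerline bounds {lo}..{hi} need a "
            f"{margin:.2f} um margin inside extent {extent}"
        )
    return pts


def make_phantom(spec: FiberPhantomSpec, shape=(128, 128, 128),
                 spacing=(0.25, 0.25, 0.25)) -> tuple[ImageVolume, PhantomTruth]:
    """Render one phantom fiber and its ground truth.

    The analytic centerline is sampled finely, the tube rendered by
    thresholding distance-to-centerline at the radius (the ground-truth
    mask), intensity set to ``contrast`` inside, gap intervals suppressed,
    the field blurred by ``blur_sigma_um`` and Gaussian noise added with
    the spec's fixed seed.  Ground-truth waviness/tilt/orientation come
    from the continuous centerline, not the raster.
    """
    pts = _fine_samples(spec)
    pts = _place_centerline(spec, pts, shape, spacing)
    curve = Curve3D(pts)
    radius_at = np.atleast_1d(spec.radius_value(curve.arc_length))
    if radius_at.size == 1:
        radius_at = np.full(len(pts), float(radius_at))
    mask = _render_tube_mask(pts, radius_at, shape, spacing)

    field_ = mask.astype(float) * float(spec.contrast)
    if spec.gaps:
        tree = cKDTree(pts)
        sz, sy, sx = spacing
        vox_idx = np.argwhere(mask)
        vox_phys = np.stack([vox_idx[:, 2] * sx, vox_idx[:, 1] * sy,
                             vox_idx[:, 0] * sz], axis=1)
        _, nearest = tree.query(vox_phys)
        s_at = curve.arc_length[nearest]
        kill = np.zeros(len(vox_idx), dtype=bool)
        for start, length in spec.gaps:
            kill |= (s_at >= start) & (s_at <= start + length)
        field_[tuple(vox_idx[kill].T)] = 0.0
    if spec.blur_sigma_um > 0:
        field_ = ndimage.gaussian_filter(
            field_, sigma=[spec.blur_sigma_um / s for s in spacing])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        field_ = field_ + rng.normal(0.0, spec.noise_sigma, size=field_.shape)
        field_ = np.clip(field_, 0.0, None)
    volume = ImageVolume(field_.astype(np.float32), spacing)
    truth = _analytic_truth(spec, pts, BinaryMask(mask))
    return volume, truth


def make_branching_mask(trunk_spec: FiberPhantomSpec,
                        branch_specs: list[FiberPhantomSpec],
                        shape=(128, 128, 128), spacing=(0.25, 0.25, 0.25)):
    """Union tube mask of a trunk plus attached branches, with labels.

    Each branch must attach on the trunk (its first centerline point inside
    the trunk tube).  Returns ``(mask, labels, trunk_length_um)`` where
    ``labels`` is 0 background, 1 trunk, 2.. branches, trunk voxels taking
    precedence; the recorded trunk path length is the ground truth for
    branch-trimming tests.
    """
    trunk_pts = _place_centerline(trunk_spec, _fine_samples(trunk_spec),
                                  shape, spacing)
    trunk_curve = Curve3D(trunk_pts)
    trunk_r = np.atleast_1d(trunk_spec.radius_value(trunk_curve.arc_length))
    if trunk_r.size == 1:
        trunk_r = np.full(len(trunk_pts), float(trunk_r))
    trunk_mask = _render_tube_mask(trunk_pts, trunk_r, shape, spacing)
    labels = trunk_mask.astype(np.uint8)

    trunk_tree = cKDTree(trunk_pts)
    union = trunk_mask.copy()
    for bi, bspec in enumerate(branch_specs, start=2):
        if bspec.start_um is None:
            raise ValueError("branch specs must set start_um on the trunk")
        bpts = bspec.centerline(
            np.linspace(0.0, bspec.length_um,
                        max(int(bspec.length_um / _FINE_STEP_UM), 64)))
        bpts = bpts + np.asarray(bspec.start_um, dtype=float)
        d0, i0 = trunk_tree.query(bpts[0])
        if d0 > trunk_r[i0]:
            raise ValueError(
                f"branch {bi - 1} is disjoint from the trunk "
                f"(attachment distance {d0:.2f} um)")
        bcurve = Curve3D(bpts)
        br = np.atleast_1d(bspec.radius_value(bcurve.arc_length))
        if br.size == 1:
            br = np.full(len(bpts), float(br))
        bmask = _render_tube_mask(bpts, br, shape, spacing)
        labels[bmask & ~union] = bi
        union |= bmask
    return BinaryMask(union), labels, trunk_curve.total_length


def preset(name: str, seed: int = 0, noise_sigma: float = 10.0) -> FiberPhantomSpec:
    """Named phantom presets at the scales the pipeline targets."""
    presets = {
        "straight": dict(kind="straight", length_um=25.0, tilt_deg=0.0,
                         orientation_deg=20.0),
        "wavy": dict(kind="sinusoidal", length_um=24.0,
                     amplitude_um=amplitude_for_waviness(1.37, 12.0),
                     wavelength_um=12.0, tilt_deg=5.0, orientation_deg=20.0),
        "tilted": dict(kind="straight", length_um=25.0, tilt_deg=5.0,
                       orientation_deg=110.0),
        "helical": dict(kind="helical", length_um=24.0, amplitude_um=1.5,
                        wavelength_um=12.0, tilt_deg=0.0, orientation_deg=20.0),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(presets)}")
    return FiberPhantomSpec(radius_um=1.3, contrast=200.0, blur_sigma_um=0.25,
                            noise_sigma=noise_sigma, seed=seed, **presets[name])
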