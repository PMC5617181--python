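"""End-to-end driver: reslice → segment → 3D skeleton → measure.

Given a rough initial centerline per fiber, the volume is resliced along
consistency-optimized cross-sectional planes, the fiber segmented in
resliced space (where it appears straightened and compact), the mask
mapped back to original space, a sub-voxel skeleton extracted, trimmed to
its main trunk and spline-refined.  By default the reslice → skeleton pass
is repeated once with the refined skeleton as the new reslicing curve
before morphometry.  Every stage writes its intermediates when an output
directory is configured, and a run is deterministic given its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from . import frames as fr
from . import morphometry as mm
from . import segmentation as seg
from . import skeleton3d as sk
from .volume_io import ImageVolume, MeasurementTable, save_stack

__all__ = ["PipelineConfig", "FiberResult", "run_pipeline", "load_centerline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; fully serializable to YAML.

    ``centerline_units`` selects whether centerline CSV coordinates are
    voxel indices or μm.  ``plane_halfwidth_um`` is the half-extent of the
    cross-sectional sampling plane (default 6 μm, comfortably over twice a
    typical fiber radius so the whole cross section is captured).
    """

    stack: str | None = None
    centerlines: list = field(default_factory=list)
    spacing: tuple = (0.25, 0.25, 0.25)
    centerline_units: str = "um"            # "um" | "voxel"
    plane_halfwidth_um: float = 6.0
    inplane_spacing_um: float | None = None  # default: min voxel spacing
    interpolation: str = "trilinear"
    binarize_method: str = "half_max"
    min_component_size: int = 30
    closing_radius: int = 1
    spline_factor: int = 3
    diameter_outlier_um: float = 6.0
    refine_iterations: int = 1
    mesh_smoothing_iters: int = 10
    out_dir: str | None = None
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data = {k: v for k, v in data.items()
                if k in {f.name for f in dataclasses.fields(cls)}}
        if "spacing" in data:
            data["spacing"] = tuple(data["spacing"])
        return cls(**data)


@dataclass
class FiberResult:
    """Artifacts of one fiber's pass through the pipeline."""

    fiber_id: object
    morphometry: mm.FiberMorphometry
    skeleton: fr.Curve3D
    mask: seg.BinaryMask
    mesh: mm.SurfaceMesh
    reslice: fr.ResliceStack
    warnings: list = field(default_factory=list)


def load_centerline(path: str, spacing, units: str = "um") -> np.ndarray:
    """Read an initial centerline: one ``x y z`` (or ``x,y,z``) point per line.

    Voxel-unit coordinates are converted to μm with the given ``(z, y, x)``
    spacing.
    """
    pts = np.loadtxt(path, delimiter="," if _is_csv(path) else None, ndmin=2)
    if pts.shape[1] != 3:
        raise ValueError("centerline file must have three columns: x y z")
    if units == "voxel":
        sz, sy, sx = spacing
        pts = pts * np.array([sx, sy, sz])
    elif units != "um":
        raise ValueError("centerline_units must be 'um' or 'voxel'")
    return pts


def _is_csv(path: str) -> bool:
    try:
        with open(path) as fh:
            return "," in fh.readline()
    except OSError:
        return False


def _densify(curve: fr.Curve3D, target_step: float) -> fr.Curve3D:
    """Spline-resample so consecutive points are ~target_step apart."""
    n_now = len(curve)
    n_target = max(int(np.ceil(curve.total_length / target_step)) + 1, 2)
    if n_now >= n_target or n_now < 4:
        return curve
    factor = int(np.ceil(n_target / n_now))
    return sk.resample_spline(curve, factor=factor)


def _reslice_along(volume: ImageVolume, curve: fr.Curve3D,
                   cfg: PipelineConfig) -> fr.ResliceStack:
    ds = cfg.inplane_spacing_um or min(volume.spacing)
    half = max(int(round(cfg.plane_halfwidth_um / ds)), 1)
    tangents = fr.compute_tangents(curve)
    framefield = fr.propagate_consistent_frames(curve, tangents)
    grid = fr.build_plane_grid(half, half, ds)
    return fr.reslice_volume(volume, curve, framefield, grid,
                             interpolation=cfg.interpolation)


def _mask_to_original_space(mask_resliced: np.ndarray, stack: fr.ResliceStack,
                            volume: ImageVolume,
                            cfg: PipelineConfig) -> seg.BinaryMask:
    """Map resliced-space mask samples back and rasterize in the original grid."""
    plane = stack.planes[0]
    R, C = plane.half_extent_r, plane.half_extent_c
    ds = plane.sample_spacing
    sl, rr, cc = np.nonzero(mask_resliced)
    if sl.size == 0:
        raise ValueError("resliced segmentation is empty")
    pts = np.stack([sl.astype(float), (cc - C) * ds, (rr - R) * ds], axis=1)
    cloud = fr.map_back(pts, stack)
    from .volume_io import physical_to_voxel
    idx = np.round(physical_to_voxel(cloud, volume)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=1)
    grid = np.zeros(volume.shape, dtype=bool)
    grid[tuple(idx[ok].T)] = True
    # the point cloud undersamples the voxel grid obliquely; close 1-voxel holes
    grid = ndimage.binary_closing(
        grid, structure=ndimage.generate_binary_structure(3, 3))
    return seg.BinaryMask(grid, provenance="original")


def _segment_resliced(stack: fr.ResliceStack, cfg: PipelineConfig) -> np.ndarray:
    mask = seg.binarize(stack.intensities, method=cfg.binarize_method,
                        provenance="resliced")
    mask = seg.clean_mask(mask, min_component_size=cfg.min_component_size,
                          closing_radius=cfg.closing_radius)
    data = mask.data & stack.valid
    # keep the component(s) passing through the plane centers (the fiber
    # being traced), not other fibers crossing the plane corners
    lab, nlab = ndimage.label(
        data, structure=ndimage.generate_binary_structure(3, 3))
    if nlab > 1:
        R, C = stack.planes[0].half_extent_r, stack.planes[0].half_extent_c
        center_labels = set(lab[:, R, C].ravel()) - {0}
        if center_labels:
            data = np.isin(lab, sorted(center_labels))
    return data


def _extend_to_mask_boundary(points: np.ndarray, mask: np.ndarray,
                             volume: ImageVolume,
                             max_extension_um: float = 1.5) -> np.ndarray:
    """Prolong both curve ends along their local direction while still inside
    the mask.

    Endpoint detection on the arrival-time field stops a couple of voxels
    short of a blunt fiber end; walking the end tangent out to the mask
    boundary restores most of the lost length.  The walk is deliberately
    short and straight: it may not follow a strongly curving tube, which is
    why it is capped near one fiber radius.
    """
    from .volume_io import physical_to_voxel

    step = 0.5 * float(min(volume.spacing))
    shape = np.array(volume.shape)

    def inside(p):
        idx = np.round(physical_to_voxel(p, volume)).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            return False
        return bool(mask[tuple(idx)])

    out = points
    for end in (0, -1):
        ref = min(16, len(out) - 1)
        d = out[end] - (out[ref] if end == 0 else out[-1 - ref])
        n = np.linalg.norm(d)
        if n < 1e-9:
            continue
        d /= n
        p = out[end].copy()
        ext = []
        travelled = 0.0
        while travelled + step <= max_extension_um:
            cand = p + step * d
            if not inside(cand):
                break
            ext.append(cand.copy())
            p = cand
            travelled += step
        if ext:
            out = (np.vstack([ext[::-1], out]) if end == 0
                   else np.vstack([out, ext]))
    return out


def _skeletonize_original(mask: seg.BinaryMask, volume: ImageVolume,
                          cfg: PipelineConfig) -> fr.Curve3D:
    graph = sk.fast_marching_centerline(mask, volume.spacing)
    comps = graph.components()
    if len(comps) > 1:
        logger.warning("skeleton has %d components; keeping the largest",
                       len(comps))
        largest = max(comps, key=len)
        drop = [n for n in graph.g.nodes if n not in largest]
        graph.g.remove_nodes_from(drop)
    trunk = sk.trim_to_trunk(graph)
    pts = _extend_to_mask_boundary(trunk.points, mask.data, volume)
    if len(pts) >= 8:
        # decimate to one point per voxel pitch, then suppress sub-voxel
        # backtrace jitter (a pure arc-length inflation) with a ~1-voxel
        # smoothing window — far below any fiber undulation wavelength
        step = float(min(volume.spacing))
        keep = [0]
        for i in range(1, len(pts)):
            if np.linalg.norm(pts[i] - pts[keep[-1]]) >= step:
                keep.append(i)
        if keep[-1] != len(pts) - 1:
            keep.append(len(pts) - 1)
        pts = pts[keep]
        if len(pts) >= 8:
            sm = ndimage.gaussian_filter1d(pts, sigma=1.0, axis=0,
                                           mode="nearest")
            sm[0], sm[-1] = pts[0], pts[-1]
            pts = sm
    dedup = np.ones(len(pts), bool)
    dedup[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    trunk = fr.Curve3D(pts[dedup])
    if len(trunk) >= 4:
        trunk = sk.resample_spline(trunk, factor=cfg.spline_factor)
    return trunk


def _measure(mask: seg.BinaryMask, skeleton: fr.Curve3D, volume: ImageVolume,
             cfg: PipelineConfig, fiber_id) -> tuple[mm.FiberMorphometry, mm.SurfaceMesh]:
    mesh = mm.mesh_from_mask(mask, volume.spacing,
                             smoothing_iters=cfg.mesh_smoothing_iters)
    morpho = mm.measure_csa_series(mesh, skeleton,
                                   diameter_outlier_um=cfg.diameter_outlier_um,
                                   fiber_id=fiber_id)
    proj = mask.data.any(axis=0)   # XY maximum-intensity projection
    try:
        morpho.orientation_deg = mm.orientation_2d(proj)
    except ValueError:
        morpho.orientation_deg = np.nan
    return morpho, mesh


def process_fiber(volume: ImageVolume, initial_points: np.ndarray,
                  cfg: PipelineConfig, fiber_id=0) -> FiberResult:
    """Run the full reslice → segment → skeleton → measure chain for one fiber."""
    curve = fr.Curve3D(initial_points)
    curve = _densify(curve, target_step=min(volume.spacing))
    stack = mask = None
    for it in range(cfg.refine_iterations + 1):
        stage = "reslice"
        try:
            stack = _reslice_along(volume, curve, cfg)
            stage = "segment"
            resliced_mask = _segment_resliced(stack, cfg)
            stage = "map_back"
            mask = _mask_to_original_space(resliced_mask, stack, volume, cfg)
            stage = "skeleton"
            curve = _skeletonize_original(mask, volume, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed for fiber {fiber_id!r} "
                f"(iteration {it}): {exc}") from exc
    try:
        morpho, mesh = _measure(mask, curve, volume, cfg, fiber_id)
    except Exception as exc:
        raise RuntimeError(
            f"stage 'measure' failed for fiber {fiber_id!r}: {exc}") from exc
    return FiberResult(fiber_id=fiber_id, morphometry=morpho, skeleton=curve,
                       mask=mask, mesh=mesh, reslice=stack)


def run_pipeline(config: PipelineConfig,
                 volume: ImageVolume | None = None,
                 centerlines: list | None = None) -> MeasurementTable:
    """Execute the pipeline for every configured fiber.

    ``volume``/``centerlines`` may be passed in memory; otherwise they are
    loaded from the paths in the config.  The resolved config and all
    intermediates are written beside the outputs when ``out_dir`` is set.
    A failing stage aborts with the stage name and fiber id; results for
    fibers already processed are retained in the written table.
    """
    from .volume_io import load_stack

    if volume is None:
        if config.stack is None:
            raise ValueError("no stack path configured and no volume passed")
        volume = load_stack(config.stack, config.spacing)
    if centerlines is None:
        centerlines = [load_centerline(p, config.spacing,
                                       config.centerline_units)
                       for p in config.centerlines]
    if not centerlines:
        raise ValueError("no centerlines to process")

    out_dir = config.out_dir
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        config.to_yaml(os.path.join(out_dir, "resolved_config.yaml"))

    table = MeasurementTable()
    series_rows = []
    try:
        for fid, pts in enumerate(centerlines):
            result = process_fiber(volume, np.asarray(pts, float), config,
                                   fiber_id=fid)
            m = result.morphometry
            table.add(fid, "waviness", m.waviness, "dimensionless")
            table.add(fid, "tilt", m.tilt_deg, "degree")
            if np.isfinite(m.orientation_deg):
                table.add(fid, "orientation", m.orientation_deg, "degree")
            csa_mean, csa_sd = m.csa_mean_sd
            d_mean, d_sd = m.diameter_mean_sd
            table.add(fid, "csa_mean", csa_mean, "um^2")
            table.add(fid, "csa_sd", csa_sd, "um^2")
            table.add(fid, "diameter_mean", d_mean, "um")
            table.add(fid, "diameter_sd", d_sd, "um")
            table.add(fid, "outlier_fraction", m.outlier_fraction,
                      "dimensionless")
            for i in range(len(m.csa_um2)):
                series_rows.append(
                    dict(fiber_id=fid, point_index=i,
                         arc_length_um=m.arc_length_um[i],
                         csa_um2=m.csa_um2[i], diameter_um=m.diameter_um[i],
                         outlier=bool(m.outlier[i])))
            if out_dir:
                _write_fiber_artifacts(result, out_dir)
            logger.info("fiber %d: w=%.3f tilt=%.2f deg, %d/%d CSA outliers",
                        fid, m.waviness, m.tilt_deg, int(m.outlier.sum()),
                        len(m.outlier))
    finally:
        if out_dir:
            table.to_csv(os.path.join(out_dir, "summary.csv"))
            table.to_json(os.path.join(out_dir, "summary.json"))
            if series_rows:
                import pandas as pd
                pd.DataFrame(series_rows).to_csv(
                    os.path.join(out_dir, "csa_series.csv"), index=False)
    return table


def _write_fiber_artifacts(result: FiberResult, out_dir: str) -> None:
    fid = result.fiber_id
    np.savetxt(os.path.join(out_dir, f"fiber{fid}_skeleton.csv"),
               result.skeleton.points, delimiter=",", header="x,y,z",
               comments="")
    save_stack(ImageVolume((result.mask.data * 255).astype(np.uint8),
                           (1, 1, 1)),
               os.path.join(out_dir, f"fiber{fid}_mask.tif"))
    resliced = result.reslice.intensities
    save_stack(ImageVolume(resliced.astype(np.float32), (1, 1, 1)),
               os.path.join(out_dir, f"fiber{fid}_resliced.tif"))
    transforms = [p.transform().tolist() for p in result.reslice.planes]
    with open(os.path.join(out_dir, f"fiber{fid}_transforms.json"), "w") as fh:
        json.dump(transforms, fh)
    result.mesh.export(os.path.join(out_dir, f"fiber{fid}_mesh.ply"))
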