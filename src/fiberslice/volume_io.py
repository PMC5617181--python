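"""Image-stack I/O and the coordinate convention used across the package.

Arrays are indexed ``(z, y, x)``; physical coordinates are reported as
``(x, y, z)`` in micrometres.  Voxel *centers* carry the sample: index
``(0, 0, 0)`` maps to ``origin``.  Every public measurement API works in
physical micrometres; only I/O and segmentation work in index space.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageVolume",
    "MeasurementTable",
    "load_stack",
    "save_stack",
    "voxel_to_physical",
    "physical_to_voxel",
]


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Scalar samples indexed ``(z, y, x)``.
    spacing : tuple of float
        Physical size per voxel along ``(z, y, x)`` in micrometres; all
        components must be positive.  Anisotropic spacing is supported.
    origin : tuple of float
        Physical ``(x, y, z)`` coordinate of voxel ``(0, 0, 0)`` in
        micrometres.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D (z, y, x) array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (z, y, x)")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def physical_extent(self) -> np.ndarray:
        """Physical ``(x, y, z)`` coordinates of the last voxel center."""
        nz, ny, nx = self.shape
        return voxel_to_physical((nz - 1, ny - 1, nx - 1), self)


def load_stack(path: str | os.PathLike, spacing) -> ImageVolume:
    """Read a multi-page TIFF (or a directory of single-page TIFFs in z order).

    Intensities are preserved bit-exact for integer inputs.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If pages have inconsistent dimensions.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.isdir(path):
        pages = sorted(
            f for f in os.listdir(path) if f.lower().endswith((".tif", ".tiff"))
        )
        if not pages:
            raise FileNotFoundError(f"no TIFF files in directory {path!r}")
        slices = [tifffile.imread(os.path.join(path, f)) for f in pages]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent page dimensions: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 3D stack, got shape {data.shape}")
    return ImageVolume(data, spacing)


def save_stack(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write the volume as a multi-page TIFF, one page per z slice."""
    data = np.asarray(volume.intensities)
    tifffile.imwrite(os.fspath(path), data, photometric="minisblack")


def voxel_to_physical(index, volume: ImageVolume) -> np.ndarray:
    """Map (possibly fractional) ``(z, y, x)`` indices to physical ``(x, y, z)`` μm.

    The map is affine, ``index * spacing + origin`` with the axis flip, and
    is exactly inverted by :func:`physical_to_voxel`.  Extrapolation outside
    the grid is allowed for bookkeeping.
    """
    idx = np.asarray(index, dtype=float)
    sz, sy, sx = volume.spacing
    ox, oy, oz = volume.origin
    z = idx[..., 0] * sz + oz
    y = idx[..., 1] * sy + oy
    x = idx[..., 2] * sx + ox
    return np.stack([x, y, z], axis=-1)


def physical_to_voxel(point, volume: ImageVolume) -> np.ndarray:
    """Inverse of :func:`voxel_to_physical`: ``(x, y, z)`` μm → fractional ``(z, y, x)``."""
    p = np.asarray(point, dtype=float)
    sz, sy, sx = volume.spacing
    ox, oy, oz = volume.origin
    k = (p[..., 2] - oz) / sz
    j = (p[..., 1] - oy) / sy
    i = (p[..., 0] - ox) / sx
    return np.stack([k, j, i], axis=-1)


@dataclass
class MeasurementTable:
    """Per-fiber measurement records; every value carries a unit."""

    rows: list = field(default_factory=list)

    COLUMNS = ("fiber_id", "parameter", "value", "unit", "outlier")

    def add(self, fiber_id, parameter: str, value: float, unit: str,
            outlier: bool = False) -> None:
        if not unit:
            raise ValueError("every measurement value must carry a unit")
        self.rows.append(
            {
                "fiber_id": fiber_id,
                "parameter": parameter,
                "value": float(value),
                "unit": unit,
                "outlier": bool(outlier),
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.COLUMNS))

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(os.fspath(path), index=False)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump(self.rows, fh, indent=2)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "MeasurementTable":
        df = pd.read_csv(os.fspath(path))
        table = cls()
        for _, r in df.iterrows():
            table.add(r["fiber_id"], r["parameter"], r["value"], r["unit"],
                      bool(r["outlier"]))
        return table
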