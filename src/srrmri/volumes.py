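"""Volume data model, NIfTI-1 I/O and rigid B-spline resampling.

All volumes live on axis-aligned lattices: the world coordinate of voxel
index ``v`` is ``origin + v * spacing`` (mm). Files are reoriented to a
canonical RAS-like layout on load so downstream code never branches on
storage order. Oblique poses are carried by :class:`RigidTransform`, never
by the grid itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .transforms import RigidTransform

__all__ = ["VoxelGrid", "Volume", "RegionMask", "read_volume", "write_volume", "resample_to_grid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned sampling lattice: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("VoxelGrid fields must be triples")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacing entries must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axis_codes", tuple(self.axis_codes))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical field of view per axis in mm (shape * spacing)."""
        return tuple(n * d for n, d in zip(self.shape, self.spacing))

    @property
    def world_center(self) -> tuple[float, float, float]:
        return tuple(o + (n - 1) / 2.0 * d for o, n, d in zip(self.origin, self.shape, self.spacing))

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def world_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel, stacked as shape (3, *shape)."""
        idx = np.indices(self.shape, dtype=float)
        org = np.asarray(self.origin).reshape(3, 1, 1, 1)
        sp = np.asarray(self.spacing).reshape(3, 1, 1, 1)
        return org + idx * sp


@dataclass
class Volume:
    """A scalar 3D image: intensity lattice plus its sampling grid."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.shape:
            raise ValueError(f"data shape {self.data.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data must be finite (NaN-free contract)")

    def copy(self) -> "Volume":
        return Volume(self.grid, self.data.copy())


@dataclass
class RegionMask:
    """Boolean voxel selection on a grid (analysis or background region)."""

    grid: VoxelGrid
    selected: np.ndarray

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.shape != self.grid.shape:
            raise ValueError(f"mask shape {self.selected.shape} != grid shape {self.grid.shape}")

    @property
    def count(self) -> int:
        return int(self.selected.sum())


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 file, reorienting to canonical RAS-like axes.

    Raises an error naming the path for unreadable files or non-3D images.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise OSError(f"cannot read NIfTI volume at {path!s}: {exc}") from exc
    if img.ndim != 3:
        raise ValueError(f"expected 3D image at {path!s}, got {img.ndim}D with shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    affine = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in affine[:3, 3])
    codes = nib.aff2axcodes(affine)
    return Volume(VoxelGrid(data.shape, spacing, origin, codes), data)


def write_volume(v: Volume, path) -> None:
    """Write a Volume as NIfTI-1, preserving grid metadata in the affine."""
    img = nib.Nifti1Image(v.data, v.grid.affine)
    img.header.set_zooms(v.grid.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"cannot write NIfTI volume to {path!s}: {exc}") from exc


def resample_to_grid(
    v: Volume,
    target: VoxelGrid,
    transform: RigidTransform | None = None,
    order: int = 3,
) -> Volume:
    """Resample ``v`` onto ``target`` at transformed world coordinates.

    The output voxel at world position ``w`` takes the value of ``v``
    interpolated at ``transform(w)`` (identity if no transform), so the
    returned image is ``v`` composed with the transform. Interpolation is
    a B-spline of the given order (0, 1 or 3; default third order) and
    out-of-field samples are filled with 0 (background air).
    """
    if order not in (0, 1, 3):
        raise ValueError(f"interpolation order must be 0, 1 or 3, got {order}")
    pts = target.world_coordinates()
    if transform is not None and not transform.is_identity():
        pts = transform.apply_grid(pts)
    org = np.asarray(v.grid.origin).reshape(3, 1, 1, 1)
    sp = np.asarray(v.grid.spacing).reshape(3, 1, 1, 1)
    coords = (pts - org) / sp
    data = ndimage.map_coordinates(
        v.data, coords, order=order, mode="constant", cval=0.0, prefilter=(order > 1)
    )
    return Volume(target, data)


def infield_mask(
    v: Volume,
    target: VoxelGrid,
    transform: RigidTransform | None = None,
) -> np.ndarray:
    """Boolean mask of target voxels whose sample point falls inside ``v``."""
    pts = target.world_coordinates()
    if transform is not None and not transform.is_identity():
        pts = transform.apply_grid(pts)
    org = np.asarray(v.grid.origin).reshape(3, 1, 1, 1)
    sp = np.asarray(v.grid.spacing).reshape(3, 1, 1, 1)
    coords = (pts - org) / sp
    nmax = np.asarray(v.grid.shape).reshape(3, 1, 1, 1) - 1
    return np.all((coords >= 0) & (coords <= nmax), axis=0)
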