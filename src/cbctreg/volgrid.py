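"""Geometric 3D volumes and binary masks with physical-space semantics.

Axis-aligned grids only: the physical position of voxel index ``(i, j, k)``
is ``origin + (i, j, k) * spacing``; no direction-cosine rotation is
supported (deliberate — the phantom and the pelvic scans it emulates are
axis-aligned, and dropping direction cosines keeps every geometric
computation a three-term affine map).  All coordinates are physical
millimetres, indices are 0-based, and a voxel's position is its *center*.

File I/O goes through SimpleITK so MetaImage (``.mha``/``.mhd``) and
NIfTI-1 (``.nii``/``.nii.gz``) round-trip with their header geometry.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "Modality",
    "Grid",
    "ImageVolume",
    "BinaryMask",
    "StructureSet",
    "read_volume",
    "read_mask",
    "write_volume",
    "resample",
    "extract_surface_points",
]


class Modality(str, enum.Enum):
    """Image modality: CT in Hounsfield units, CBCT in (uncalibrated) arbitrary units."""

    CT = "CT"
    CBCT = "CBCT"

    #: fill value used for points outside the image support during resampling
    @property
    def air_value(self) -> float:
        return -1000.0 if self is Modality.CT else -500.0


@dataclass(frozen=True)
class Grid:
    """Geometry of an axis-aligned voxel grid (shape, spacing mm, origin mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 per axis, got {self.shape}")

    @property
    def center(self) -> np.ndarray:
        """Physical center of the grid (mm)."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)

    def points(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of integer voxel indices, shape (N, 3)."""
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(self.spacing)

    def all_points(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape (Nx*Ny*Nz, 3), C order."""
        idx = np.stack(np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1)
        return self.points(idx.reshape(-1, 3))

    def continuous_index(self, points: np.ndarray) -> np.ndarray:
        """Map physical points (N, 3) to continuous voxel indices."""
        return (np.asarray(points, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class ImageVolume:
    """A 3D scalar image with physical geometry and a modality tag.

    ``voxels`` is indexed ``[i, j, k]`` along (x, y, z); HU for CT, arbitrary
    units for CBCT.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    modality: Modality = Modality.CT

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.modality = Modality(self.modality)

    @property
    def grid(self) -> Grid:
        return Grid(self.voxels.shape, self.spacing, self.origin)

    @property
    def fill_value(self) -> float:
        return self.modality.air_value

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.voxels.copy(), self.spacing, self.origin, self.modality)


@dataclass
class BinaryMask:
    """A {0,1} mask sharing the geometric conventions of :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"mask voxels must be 3D, got ndim={v.ndim}")
        vals = np.unique(v)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, got {vals[:10]}")
        self.voxels = v.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(self.voxels.shape, self.spacing, self.origin)

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.voxels.sum())

    def centroid(self) -> np.ndarray:
        """Physical center of mass (mm) of the mask voxels."""
        if self.count() == 0:
            raise ValueError("empty structure")
        idx = np.argwhere(self.voxels > 0)
        return self.grid.points(idx).mean(axis=0)

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.voxels.copy(), self.spacing, self.origin)


STRUCTURE_NAMES = ("ctv", "rectum", "bladder", "body")


@dataclass
class StructureSet:
    """Named binary masks (ctv/prostate, rectum, bladder, body) on one grid."""

    masks: dict[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self):
        grids = [m.grid for m in self.masks.values()]
        for g in grids[1:]:
            if g != grids[0]:
                raise ValueError("all structure masks must share one grid")

    def __getitem__(self, name: str) -> BinaryMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def items(self):
        return self.masks.items()

    @property
    def grid(self) -> Grid:
        if not self.masks:
            raise ValueError("empty structure set")
        return next(iter(self.masks.values())).grid

    def shifted(self, delta: Iterable[float]) -> "StructureSet":
        """All masks with origin shifted by ``delta`` mm (voxels untouched)."""
        d = np.asarray(tuple(delta), dtype=float)
        return StructureSet(
            {
                n: BinaryMask(m.voxels, m.spacing, tuple(np.asarray(m.origin) + d))
                for n, m in self.masks.items()
            }
        )


# ---------------------------------------------------------------------------
# file I/O


_SUPPORTED_EXT = (".mha", ".mhd", ".nii", ".nii.gz")


def _check_path(path: str) -> None:
    p = str(path)
    if not any(p.endswith(e) for e in _SUPPORTED_EXT):
        raise IOError(
            f"unsupported volume format for '{p}': expected one of {_SUPPORTED_EXT}"
        )


def read_volume(path: str, modality: Modality | str = Modality.CT) -> ImageVolume:
    """Read a MetaImage or NIfTI volume; geometry taken from the header."""
    import SimpleITK as sitk

    _check_path(path)
    if not os.path.exists(str(path)):
        raise IOError(f"cannot read volume: no such file '{path}'")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - sitk error text varies
        raise IOError(f"cannot read volume '{path}': {exc}") from exc
    # sitk arrays are [z, y, x]; we store [x, y, z]
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(
        np.ascontiguousarray(arr.astype(np.float64)),
        tuple(img.GetSpacing()),
        tuple(img.GetOrigin()),
        Modality(modality),
    )


def read_mask(path: str) -> BinaryMask:
    """Read a {0,1} mask volume (values binarized at 0.5 to absorb float storage)."""
    v = read_volume(path)
    return BinaryMask((v.voxels > 0.5).astype(np.uint8), v.spacing, v.origin)


def write_volume(v: ImageVolume | BinaryMask, path: str) -> None:
    """Write a volume or mask as MetaImage/NIfTI (masks stored as uint8)."""
    import SimpleITK as sitk

    _check_path(path)
    arr = v.voxels
    if isinstance(v, BinaryMask):
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in v.spacing))
    img.SetOrigin(tuple(float(o) for o in v.origin))
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:  # pragma: no cover
        raise IOError(f"cannot write volume '{path}': {exc}") from exc


# ---------------------------------------------------------------------------
# resampling


def resample(
    v: ImageVolume | BinaryMask,
    t,  # RigidTransform; annotated loosely to avoid an import cycle
    target_grid: Grid,
    interp: str | None = None,
    fill: float | None = None,
):
    """Resample ``v`` onto ``target_grid`` through rigid transform ``t``.

    ``t`` maps *target* physical points into *source* physical space: the
    output voxel at target point q takes the source value at t(q)
    (pull-back).  Images default to linear interpolation, masks to
    nearest-neighbor (which preserves the {0,1} value set).  Points mapping
    outside the source support take ``fill`` (default: modality air value
    for images, 0 for masks).
    """
    is_mask = isinstance(v, BinaryMask)
    if interp is None:
        interp = "nearest" if is_mask else "linear"
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    params = np.concatenate([t.rotations, t.translations, t.center])
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite transform parameters")
    if fill is None:
        fill = 0.0 if is_mask else v.fill_value

    pts = target_grid.all_points()
    src_pts = t.apply(pts)
    ci = v.grid.continuous_index(src_pts)  # (N, 3)
    order = 1 if interp == "linear" else 0
    out = ndimage.map_coordinates(
        v.voxels.astype(np.float64),
        ci.T,
        order=order,
        mode="constant",
        cval=float(fill),
        prefilter=False,
    ).reshape(target_grid.shape)

    if is_mask:
        return BinaryMask(
            (out > 0.5).astype(np.uint8), target_grid.spacing, target_grid.origin
        )
    return ImageVolume(out, target_grid.spacing, target_grid.origin, v.modality)


# ---------------------------------------------------------------------------
# surface extraction


def extract_surface_points(m: BinaryMask) -> np.ndarray:
    """Physical centers (mm) of surface voxels of ``m``, shape (N, 3).

    A voxel is on the surface when it is 1 and has at least one
    six-connected neighbor equal to 0; voxels on the volume boundary count
    as adjacent to background.  Ordering is lexicographic by index, so the
    result is deterministic.
    """
    if m.count() == 0:
        raise ValueError("empty structure")
    v = m.voxels.astype(bool)
    padded = np.pad(v, 1, mode="constant", constant_values=False)
    interior = np.ones_like(v)
    for axis in range(3):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[axis] = slice(0, -2)
        hi[axis] = slice(2, None)
        interior &= padded[tuple(lo)] & padded[tuple(hi)]
    surface = v & ~interior
    idx = np.argwhere(surface)  # argwhere is lexicographic in C order
    return m.grid.points(idx)
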