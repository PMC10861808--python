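"""Volume data model, NIfTI I/O, and grid resampling.

Conventions used throughout the package:

* voxel indices are 0-based;
* world coordinates (mm) are voxel *centers* mapped through the stored
  affine;
* no automatic reorientation is applied on read — callers resample
  explicitly onto a target grid when geometries differ;
* voxels mapping outside the source extent during resampling are filled
  with 0 (background), matching mask semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "BinaryMask",
    "Grid",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "world_coords_of_foreground",
    "same_grid",
]


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not.

    The message carries both shapes and affines; call
    :func:`resample_to_grid` to reconcile them.
    """


@dataclass(frozen=True)
class Grid:
    """Target geometry for resampling: a shape plus a voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")


@dataclass
class Volume:
    """A 3D scalar grid with a voxel-to-world affine (world units mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        self._validate()

    def _validate(self) -> None:  # hook for subclasses
        pass

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm: column norms of the affine's 3x3 block."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.affine)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n x 3) to world coordinates (n x 3, mm)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ homog.T).T[:, :3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world coordinates (n x 3, mm) to continuous voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        homog = np.c_[xyz, np.ones(len(xyz))]
        return (np.linalg.inv(self.affine) @ homog.T).T[:, :3]


class BinaryMask(Volume):
    """A Volume whose voxel values are restricted to {0, 1}."""

    def _validate(self) -> None:
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            bad = vals[~np.isin(vals, (0, 1))]
            raise ValueError(f"binary mask contains values other than 0/1: {bad[:5]}")

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data))

    @classmethod
    def from_volume(cls, vol: Volume, *, threshold: float | None = None) -> "BinaryMask":
        """Coerce a volume to a mask; ``threshold`` applies ``data > threshold``."""
        data = vol.data
        if threshold is not None:
            data = (data > threshold).astype(np.uint8)
        return cls(np.asarray(data).astype(np.uint8), vol.affine)


def same_grid(a: Volume | Grid, b: Volume | Grid, *, atol: float = 1e-5) -> bool:
    """True when the two carriers share shape and affine (within ``atol``)."""
    return a.shape == b.shape and np.allclose(a.affine, b.affine, atol=atol)


def require_same_grid(a: Volume, b: Volume, what: str = "operation") -> None:
    if not same_grid(a, b):
        raise GridMismatchError(
            f"{what} requires both volumes on one grid; got shapes {a.shape} vs "
            f"{b.shape} and affines\n{a.affine}\nvs\n{b.affine}\n"
            "Use resample_to_grid() to reconcile."
        )


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 volume, preserving data and affine.

    A 4D image with a trailing singleton axis is squeezed to 3D (a notice
    is logged); any other 4D shape is an error.  No reorientation is
    applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] == 1:
            logger.info("squeezing trailing singleton axis of %s (shape %s)", path, data.shape)
            data = data[..., 0]
        else:
            raise ValueError(
                f"{path}: expected a 3D image (or trailing singleton 4th axis), got shape {data.shape}"
            )
    elif data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError(f"{path}: affine is not invertible:\n{affine}")
    return Volume(data, affine)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; lossless for integer-typed data."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    img.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def resample_to_grid(vol: Volume, target: Grid | Volume, mode: str = "linear") -> Volume:
    """Resample ``vol`` onto ``target``'s grid.

    ``mode`` is ``"nearest"`` or ``"linear"``; binary masks must use
    nearest (linear interpolation would create fractional values).
    Out-of-field voxels are filled with 0.
    """
    if mode not in ("nearest", "linear"):
        raise ValueError(f"mode must be 'nearest' or 'linear', got {mode!r}")
    is_mask = isinstance(vol, BinaryMask)
    if is_mask and mode != "nearest":
        raise ValueError("binary masks must be resampled with mode='nearest'")
    tgt = target.grid if isinstance(target, Volume) else target
    if same_grid(vol, tgt):
        out = vol.data.copy()
    else:
        # target voxel -> world -> source voxel
        matrix = np.linalg.inv(vol.affine) @ tgt.affine
        order = 0 if mode == "nearest" else 1
        out = ndimage.affine_transform(
            vol.data.astype(float),
            matrix=matrix[:3, :3],
            offset=matrix[:3, 3],
            output_shape=tgt.shape,
            order=order,
            mode="constant",
            cval=0.0,
            prefilter=False,
        )
    if is_mask:
        return BinaryMask(np.rint(out).astype(np.uint8), tgt.affine)
    return Volume(out, tgt.affine)


def world_coords_of_foreground(mask: BinaryMask) -> np.ndarray:
    """World coordinates (mm) of foreground voxel centers.

    One point per foreground voxel, ordered lexicographically by voxel
    index.  Returns an (n, 3) array (n may be 0).
    """
    idx = np.argwhere(mask.data > 0)  # argwhere is C-order == lexicographic
    if len(idx) == 0:
        return np.empty((0, 3))
    return mask.voxel_to_world(idx)
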