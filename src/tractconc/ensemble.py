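"""Aggregation of stochastic segmentation probability maps.

A :class:`ProbabilityEnsemble` holds T probability volumes (one per
stochastic inference pass) on a shared grid.  From it we derive the mean
probability map, the binary mask (strict threshold), and a voxelwise
uncertainty map — either the across-member population standard deviation
or the binary entropy of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volumes import BinaryMask, Volume, read_volume, require_same_grid, same_grid

__all__ = [
    "ProbabilityEnsemble",
    "UncertaintyMap",
    "ensemble_mean",
    "binarize",
    "uncertainty_map",
    "sample_at_mask",
]

_PROB_TOL = 1e-9


@dataclass
class ProbabilityEnsemble:
    """T probability volumes on one shared grid."""

    members: list[Volume]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")
        ref = self.members[0]
        for i, m in enumerate(self.members[1:], start=1):
            if not same_grid(ref, m):
                raise ValueError(
                    f"ensemble member {i} is on a different grid than member 0: "
                    f"{m.shape} vs {ref.shape}"
                )
        stack = self.stack()
        if stack.min() < -_PROB_TOL or stack.max() > 1 + _PROB_TOL:
            raise ValueError(
                f"probabilities must lie in [0, 1]; found range "
                f"[{stack.min():.3g}, {stack.max():.3g}]"
            )

    @property
    def T(self) -> int:
        return len(self.members)

    @property
    def affine(self) -> np.ndarray:
        return self.members[0].affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.members[0].shape

    def stack(self) -> np.ndarray:
        """(T, x, y, z) array of all members."""
        return np.stack([m.data for m in self.members], axis=0)

    @classmethod
    def from_dir(cls, path: str | Path, pattern: str = "*.nii*") -> "ProbabilityEnsemble":
        """Load one volume per file from a directory (sorted by name)."""
        files = sorted(Path(path).glob(pattern))
        if not files:
            raise FileNotFoundError(f"no ensemble members matching {pattern} in {path}")
        return cls([read_volume(f) for f in files])

    @classmethod
    def from_4d(cls, path: str | Path) -> "ProbabilityEnsemble":
        """Load a 4D NIfTI with members along the 4th axis."""
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
        return cls([Volume(data[..., t], img.affine) for t in range(data.shape[3])])


@dataclass
class UncertaintyMap:
    """Non-negative voxelwise uncertainty plus the estimator that made it."""

    volume: Volume
    estimator: str

    def __post_init__(self) -> None:
        if self.estimator not in ("std", "entropy"):
            raise ValueError(f"estimator must be 'std' or 'entropy', got {self.estimator!r}")
        if self.volume.data.min() < 0:
            raise ValueError("uncertainty values must be non-negative")


def ensemble_mean(ens: ProbabilityEnsemble) -> Volume:
    """Voxelwise arithmetic mean of the members."""
    return Volume(ens.stack().mean(axis=0), ens.affine)


def binarize(prob: Volume, tau: float = 0.5) -> BinaryMask:
    """Threshold a probability map: voxel > tau -> 1, else 0 (strict)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    if prob.data.min() < -_PROB_TOL or prob.data.max() > 1 + _PROB_TOL:
        raise ValueError("binarize expects a probability map with values in [0, 1]")
    return BinaryMask((prob.data > tau).astype(np.uint8), prob.affine)


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    out = np.zeros_like(p, dtype=float)
    interior = (p > 0) & (p < 1)
    q = p[interior]
    out[interior] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return out


def uncertainty_map(ens: ProbabilityEnsemble, estimator: str = "std") -> UncertaintyMap:
    """Voxelwise uncertainty from the ensemble.

    ``std``: population standard deviation across members (the T passes
    are the full ensemble, not a sample).  ``entropy``: binary entropy of
    the ensemble mean, in bits, with 0*log2(0) := 0.
    """
    if estimator == "std":
        if ens.T < 2:
            raise ValueError("std uncertainty requires at least 2 ensemble members")
        data = ens.stack().std(axis=0, ddof=0)
    elif estimator == "entropy":
        data = _binary_entropy(ensemble_mean(ens).data)
    else:
        raise ValueError(f"estimator must be 'std' or 'entropy', got {estimator!r}")
    return UncertaintyMap(Volume(data, ens.affine), estimator)


def sample_at_mask(field: Volume, where: BinaryMask) -> np.ndarray:
    """Values of ``field`` at the foreground voxels of ``where``.

    One value per foreground voxel, in lexicographic voxel order.
    """
    require_same_grid(field, where, "sampling at mask")
    return np.asarray(field.data[where.data > 0], dtype=float)
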