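"""Reading, thresholding and summarizing probabilistic atlas volumes.

This is the optional real-data path: deposited probabilistic masks of the
subthalamic nucleus and substantia nigra (or any scalar NIfTI volume) can
be loaded, thresholded into binary masks, reduced to millimetre centers
of mass, and combined into two-rater conjunct masks.  Synthetic volumes
produced by :mod:`nucmix.anatomy` go through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import BinaryMask, VoxelGrid

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "mask_to_nifti",
    "write_mask",
    "threshold_probability",
    "conjunct_masks",
    "center_of_mass_mm",
]


@dataclass
class Volume:
    """Scalar 3-D volume with a voxel -> mm affine.

    ``is_probability`` declares the data as a probability map, enforcing
    values in [0, 1].
    """

    data: np.ndarray = field(repr=False)
    affine: np.ndarray = field(repr=False)
    space: str = "MNI"
    is_probability: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.is_probability and (self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9):
            raise ValueError(
                f"probability map values outside [0, 1]: "
                f"min={self.data.min():g}, max={self.data.max():g}"
            )

    @classmethod
    def from_grid(cls, grid: VoxelGrid, data: np.ndarray, **kw) -> "Volume":
        return cls(data=data, affine=grid.affine, **kw)

    def to_grid(self) -> VoxelGrid:
        """Interpret the affine as a regular axis-aligned grid.

        Raises if the affine has rotation/shear or negative scales (i.e.
        is not RAS axis-aligned); reorient with :func:`read_volume` first.
        """
        lin = self.affine[:3, :3]
        off_diag = lin - np.diag(np.diag(lin))
        if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(lin))):
            raise ValueError("volume affine is not axis-aligned; cannot build a VoxelGrid")
        spacing = np.diag(lin)
        if np.any(spacing <= 0):
            raise ValueError("volume affine is not in RAS orientation")
        return VoxelGrid(
            shape=self.data.shape, spacing=tuple(spacing), origin=tuple(self.affine[:3, 3])
        )


def read_volume(path, is_probability: bool = False, space: str = "MNI") -> Volume:
    """Load a NIfTI-1/NIfTI-2 volume, reoriented to RAS.

    Orientation is normalized with nibabel's closest-canonical transform
    so voxel axes run left->right, posterior->anterior, inferior->superior.
    Declaring ``is_probability`` validates the value range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return Volume(data=data, affine=np.asarray(img.affine), space=space, is_probability=is_probability)


def write_volume(vol: Volume, path) -> None:
    """Write a volume as NIfTI-1 (float32)."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def mask_to_nifti(mask: BinaryMask) -> nib.Nifti1Image:
    """Binary mask as a uint8 NIfTI-1 image with its mm affine."""
    return nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)


def write_mask(mask: BinaryMask, path) -> None:
    nib.save(mask_to_nifti(mask), str(path))


def threshold_probability(vol: Volume, level: float) -> BinaryMask:
    """Binarize a probability map: voxel included iff probability > level.

    The inequality is strict, so level 0 gives the support of the map and
    level 1 gives an empty mask (consistent with "x% probability" isoline
    semantics).
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"threshold level must be in [0, 1], got {level}")
    grid = vol.to_grid()
    return BinaryMask(grid=grid, data=(vol.data > level).astype(np.uint8))


def conjunct_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Two-rater conjunct mask: voxels present in both segmentations."""
    if not a.same_grid(b):
        raise ValueError("conjunct masks must share one grid")
    return BinaryMask(grid=a.grid, data=a.data & b.data)


def center_of_mass_mm(vol: Volume) -> np.ndarray:
    """Intensity-weighted center of mass in world (mm) coordinates.

    Works for any invertible affine: each voxel's world coordinate is
    weighted by its (non-negative) intensity.
    """
    w = vol.data
    if np.any(w < 0):
        raise ValueError("center of mass requires non-negative intensities")
    total = w.sum()
    if total <= 0:
        raise ValueError("center of mass of an empty volume is undefined")
    idx = np.argwhere(w > 0).astype(float)
    weights = w[w > 0]
    homog = np.c_[idx, np.ones(len(idx))]
    world = homog @ vol.affine.T
    return (world[:, :3] * weights[:, None]).sum(axis=0) / total
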