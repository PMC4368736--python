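"""Voxel grids and binary masks on a millimetre world frame.

A :class:`VoxelGrid` is a regular, axis-aligned lattice in MNI/RAS world
coordinates: integer index ``(i, j, k)`` maps to millimetres as
``origin + index * spacing``.  A :class:`BinaryMask` pairs a grid with a
0/1 occupancy array.  These are deliberately lightweight; heavier I/O
(NIfTI) lives in :mod:`nucmix.atlas`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "BinaryMask", "make_grid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice with an index -> mm affine.

    Parameters
    ----------
    shape :
        Number of voxels along each axis.
    spacing :
        Voxel size in mm along each axis; strictly positive.
    origin :
        World (mm, RAS) coordinate of the *center* of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("grid shape, spacing and origin must be 3-vectors")
        if any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be positive, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (diagonal, RAS)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_mm(self, index) -> np.ndarray:
        """World coordinate (mm) of the center of voxel ``index``."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def mm_to_index(self, mm) -> np.ndarray:
        """Fractional voxel index of world coordinate ``mm``."""
        mm = np.asarray(mm, dtype=float)
        return (mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coords(self, axis: int) -> np.ndarray:
        """1-D array of voxel-center world coordinates along ``axis``."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def contains_mm(self, mm) -> bool:
        """True if ``mm`` lies within the grid's voxel-center bounding box."""
        idx = self.mm_to_index(mm)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.shape) - 0.5))


@dataclass
class BinaryMask:
    """0/1 occupancy on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"mask data shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        self.data = (data != 0).astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        """Realized volume: voxel count times voxel volume."""
        return self.n_voxels * self.grid.voxel_volume

    def is_empty(self) -> bool:
        return self.n_voxels == 0

    def voxel_coords_mm(self) -> np.ndarray:
        """(n, 3) world coordinates of the centers of all in-mask voxels."""
        idx = np.argwhere(self.data)
        return idx * np.asarray(self.grid.spacing) + np.asarray(self.grid.origin)

    def center_of_mass_mm(self) -> np.ndarray:
        """Unweighted (binary) center of mass, in mm."""
        if self.is_empty():
            raise ValueError("center of mass of an empty mask is undefined")
        return self.voxel_coords_mm().mean(axis=0)

    def same_grid(self, other: "BinaryMask") -> bool:
        return self.grid == other.grid


def make_grid(bounding_box, spacing=(0.5, 0.5, 0.5)) -> VoxelGrid:
    """Build a grid covering an axis-aligned mm bounding box.

    Parameters
    ----------
    bounding_box :
        ``((xmin, xmax), (ymin, ymax), (zmin, zmax))`` in mm.  The caller is
        responsible for including enough margin (>= 4 sigma of the widest
        smoothing kernel) so that smoothing never truncates at the boundary.
    spacing :
        Voxel size in mm; scalar or per-axis triple.

    Returns
    -------
    VoxelGrid
        Grid whose voxel centers start at each axis minimum and whose extent
        covers the box (the last voxel center is at or beyond each maximum).
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if np.any(spacing <= 0):
        raise ValueError(f"voxel spacing must be strictly positive, got {tuple(spacing)}")
    box = np.asarray(bounding_box, dtype=float)
    if box.shape != (3, 2):
        raise ValueError("bounding_box must be ((xmin,xmax),(ymin,ymax),(zmin,zmax))")
    extents = box[:, 1] - box[:, 0]
    if np.any(extents < spacing):
        raise ValueError("bounding box smaller than one voxel")
    shape = tuple(int(np.ceil(e / s)) for e, s in zip(extents, spacing))
    return VoxelGrid(shape=shape, spacing=tuple(spacing), origin=tuple(box[:, 0]))
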