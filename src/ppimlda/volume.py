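"""Voxel grids with world-space affines.

A :class:`VolumeGrid` is the common substrate for every spatial object in the
package: BOLD runs (4D), statistic maps, tissue-probability maps and binary
masks (3D).  Data are stored in ``(x, y, z[, t])`` axis order, matching the
array layout nibabel exposes for NIfTI-1 images, and the affine maps 0-based
voxel indices to world (MNI) millimetre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from nibabel.affines import apply_affine


@dataclass
class VolumeGrid:
    """A 3D or 4D voxel array plus its voxel-to-world affine.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz)`` or ``(nx, ny, nz, nt)``.
    affine:
        4x4 voxel-to-world matrix (homogeneous coordinates, millimetres).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"VolumeGrid requires 3D or 4D data, got ndim={self.data.ndim}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular; voxel size would be zero")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def n_volumes(self) -> int:
        """Number of time points (1 for a 3D map)."""
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return apply_affine(self.affine, np.asarray(ijk, dtype=float))

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return apply_affine(np.linalg.inv(self.affine), np.asarray(xyz, dtype=float))

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid on the same affine."""
        return VolumeGrid(np.asarray(data), self.affine.copy())


def voxel_centers_mm(grid: VolumeGrid) -> np.ndarray:
    """World coordinates of every voxel center, shape ``grid.shape3d + (3,)``."""
    nx, ny, nz = grid.shape3d
    ijk = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    )
    return grid.voxel_to_world(ijk)


def default_affine(voxel_size_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Axis-aligned affine with the given voxel size and world origin at voxel (0,0,0)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    aff[:3, 3] = origin_mm
    return aff
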