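"""Voxel grid geometry shared by phantoms, kernels and dose volumes."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis.
    spacing : tuple of float
        Voxel pitch in mm along each axis; strictly positive.
    origin : tuple of float
        World (mm) coordinate of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(float(s) <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def center_index(self) -> tuple[int, int, int]:
        return tuple(int(n) // 2 for n in self.shape)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for integer indices ``idx`` (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world coordinates ``pos`` (..., 3)."""
        pos = np.asarray(pos, dtype=float)
        idx = np.rint((pos - np.asarray(self.origin)) / np.asarray(self.spacing))
        return idx.astype(int)

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx)
        ok = np.ones(idx.shape[:-1], dtype=bool)
        for ax in range(3):
            ok &= (idx[..., ax] >= 0) & (idx[..., ax] < self.shape[ax])
        return ok

    def axes_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            np.arange(self.shape[ax]) * self.spacing[ax] + self.origin[ax] for ax in range(3)
        )

    def affine(self) -> np.ndarray:
        """4x4 affine mapping voxel indices to world mm (for NIfTI I/O)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff
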