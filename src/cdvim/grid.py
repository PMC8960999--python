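"""Voxel grid with a world affine.

World axes follow the stereotactic convention used throughout the package:
+x = right (medio-lateral, ML), +y = anterior (anterior-posterior, AP),
+z = superior (superior-inferior, SI).  All reported coordinates use
voxel-to-world mapping; voxel indices are 0-based and mask membership of a
continuous point is decided by the voxel containing it (floor under the
inverse affine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel lattice plus its voxel-to-world affine (mm)."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4, mm

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths in mm along each voxel axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm (..., 3) to continuous voxel coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        inv = self.inverse_affine
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def containing_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Integer voxel index containing each continuous world point."""
        return np.floor(self.world_to_voxel(xyz) + 0.5).astype(np.int64)

    def inside(self, ijk: np.ndarray) -> np.ndarray:
        """Boolean mask of indices that fall inside the grid."""
        ijk = np.asarray(ijk)
        return np.all((ijk >= 0) & (ijk < np.asarray(self.dims)), axis=-1)

    def voxel_centres_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape dims + (3,)."""
        ii, jj, kk = np.meshgrid(*(np.arange(d) for d in self.dims), indexing="ij")
        ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.voxel_to_world(ijk).reshape(*self.dims, 3)

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine, atol=atol)


def default_grid(dims: tuple[int, int, int] = (64, 64, 64), voxel_mm: float = 1.25) -> VolumeGrid:
    """Isotropic grid with the world origin (the MCP) at the central voxel."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    centre = (np.asarray(dims) // 2).astype(float)
    affine[:3, 3] = -voxel_mm * centre
    return VolumeGrid(tuple(dims), affine)
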