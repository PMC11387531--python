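"""Voxel grids and world/voxel coordinate geometry.

All volumes in this package live on axis-aligned grids described by an
:class:`ImageGrid`: array shape, voxel size in mm and world origin in mm
(RAS-style right-handed axes).  Rotations between modalities are carried by
rigid transforms (see :mod:`prmivim.register`), not by oblique grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid"]


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of a 3D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Array shape (nx, ny, nz).
    voxel_size : tuple of float
        Voxel edge lengths (dx, dy, dz) in mm; must be positive.
    origin : tuple of float
        World coordinates (mm) of the center of voxel (0, 0, 0).
    orientation : str
        Axis-orientation tag; only right-handed ``"RAS"`` is produced here.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = field(default="RAS")

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal scaling + origin)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz / 1000.0

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def center_world(self) -> np.ndarray:
        """World coordinates of the grid's geometric center."""
        return self.voxel_to_world((np.asarray(self.shape) - 1) / 2.0)

    @classmethod
    def from_affine(cls, shape, affine: np.ndarray) -> "ImageGrid":
        """Build a grid from an axis-aligned NIfTI affine.

        Raises if the affine carries rotation/shear (this package keeps all
        inter-modality rotation in explicit rigid transforms).
        """
        affine = np.asarray(affine, dtype=float)
        lin = affine[:3, :3]
        offdiag = lin - np.diag(np.diag(lin))
        if np.max(np.abs(offdiag)) > 1e-6 * max(1.0, np.max(np.abs(lin))):
            raise ValueError("oblique affines are not supported; supply an explicit rigid transform")
        voxel = np.diag(lin)
        if np.any(voxel <= 0):
            raise ValueError("affine must have positive diagonal voxel scales (RAS)")
        return cls(tuple(int(s) for s in shape[:3]), tuple(voxel), tuple(affine[:3, 3]))
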