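"""Volume containers and NIfTI-1 input/output.

A :class:`VolumeGrid` couples a 3-D scalar array with a 4x4 voxel-to-world
affine (mm).  Displacement fields are stored as 4-D arrays with the vector
component on the last axis, in millimetres, following the convention
``y(x) = x + u(x)`` (the field maps early-time-point coordinates into the
late image).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "load_volume", "save_volume", "save_field", "load_field"]


@dataclass
class VolumeGrid:
    """A 3-D scalar volume on a regular grid.

    Parameters
    ----------
    data:
        3-D array of finite values.
    affine:
        Invertible 4x4 voxel-index -> world (mm) map.  Defaults to identity
        (1 mm isotropic voxels at the origin).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (per axis)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new volume with the same affine."""
        return VolumeGrid(np.asarray(data, dtype=float), self.affine.copy())


def load_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(np.asanyarray(img.dataobj, dtype=float), img.affine)


def save_volume(vol: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def save_field(u: np.ndarray, affine: np.ndarray, path) -> None:
    """Save a displacement field as a 4-D NIfTI, components on the last axis (mm)."""
    u = np.asarray(u, dtype=np.float32)
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ValueError("field must have shape (nx, ny, nz, 3)")
    nib.save(nib.Nifti1Image(u, np.asarray(affine, dtype=float)), str(path))


def load_field(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    u = np.asanyarray(img.dataobj, dtype=float)
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ValueError("field file must be 4-D with 3 components on the last axis")
    return u, img.affine
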