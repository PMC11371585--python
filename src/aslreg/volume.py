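"""Minimal 3-D volume container with a voxel-to-world affine (RAS mm).

Wraps a numpy array plus the NIfTI-style 4x4 affine; I/O goes through
nibabel so files interoperate with standard neuroimaging tools.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class Volume:
    """A 3-D scalar image with world coordinates.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values (T1w-like intensity, M0, delta-M, or CBF in
        mL/100g/min depending on context).
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm (RAS) mapping.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        return Volume(
            self.data.copy() if data is None else np.asarray(data, float),
            self.affine.copy(),
        )

    # ---- coordinate helpers -------------------------------------------------

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world mm."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_grid(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nvox, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T.astype(float)
        return self.voxel_to_world(idx)

    def sample_world(
        self, xyz: np.ndarray, order: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear-sample the volume at world points.

        Returns (values, inside) where ``inside`` flags points whose voxel
        coordinates fall within the grid; outside points get value 0.
        """
        vox = self.world_to_voxel(xyz)
        inside = np.all(
            (vox >= 0) & (vox <= np.array(self.shape, float) - 1), axis=1
        )
        vals = ndimage.map_coordinates(
            self.data, vox.T, order=order, mode="constant", cval=0.0
        )
        return vals, inside

    # ---- I/O ----------------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj, dtype=float), img.affine)


def centered_affine(shape, spacing) -> np.ndarray:
    """Axis-aligned affine placing the grid's center at the world origin."""
    shape = np.asarray(shape, float)
    spacing = np.asarray(spacing, float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = -spacing * (shape - 1) / 2.0
    return aff
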