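"""World-coordinate linear transforms (rigid and affine) and resampling.

Conventions
-----------
* A transform ``T`` maps moving-space world points to fixed-space world
  points: ``point_fixed = T(point_moving)``.
* Rigid transforms are parameterized by three Euler angles in degrees
  (intrinsic x-y-z), three translations in mm, and a rotation center in
  world mm — matching the 6-degree-of-freedom head-motion model used in
  FSL-style rigid registration.
* Resampling pulls values: the output grid is traversed and the moving
  image is trilinearly interpolated at ``T^{-1}(world)``, so each output
  voxel is computed exactly once (single resampling).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .volume import Volume


class AffineTransform:
    """A general invertible linear map of world coordinates."""

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        self.matrix = matrix

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix)

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}(\n{self.matrix!r})"

    def save(self, path) -> None:
        """Write the 4x4 world matrix as plain text (row-major)."""
        np.savetxt(str(path), self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(str(path)))


@dataclass
class RigidTransform(AffineTransform):
    """6-DOF rigid world transform: rotation (deg) about ``center`` then
    translation (mm)."""

    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation_deg = np.asarray(self.rotation_deg, float).reshape(3)
        self.translation_mm = np.asarray(self.translation_mm, float).reshape(3)
        self.center_mm = np.asarray(self.center_mm, float).reshape(3)
        rot = Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()
        mat = np.eye(4)
        mat[:3, :3] = rot
        mat[:3, 3] = self.translation_mm + self.center_mm - rot @ self.center_mm
        self.matrix = mat

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Recover rigid parameters from a 4x4 matrix (must be orthonormal)."""
        matrix = np.asarray(matrix, float)
        rot = matrix[:3, :3]
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
            raise ValueError("matrix is not rigid (rotation block not orthonormal)")
        angles = Rotation.from_matrix(rot).as_euler("xyz", degrees=True)
        center = np.asarray(center_mm, float)
        trans = matrix[:3, 3] - center + rot @ center
        return cls(angles, trans, center)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix), self.center_mm)

    def compose(self, other: AffineTransform) -> AffineTransform:
        out = self.matrix @ other.matrix
        if isinstance(other, RigidTransform):
            return RigidTransform.from_matrix(out, self.center_mm)
        return AffineTransform(out)


def rotation_angle_deg(matrix: np.ndarray) -> float:
    """Magnitude of the rotation encoded in a 4x4 (or 3x3) matrix, degrees."""
    rot = np.asarray(matrix, float)
    if rot.shape == (4, 4):
        rot = rot[:3, :3]
    return float(np.degrees(Rotation.from_matrix(rot).magnitude()))


def transform_residual(
    estimated: AffineTransform,
    truth: AffineTransform,
    reference_point=(0.0, 0.0, 0.0),
) -> tuple[float, float]:
    """Misalignment of ``estimated`` relative to ``truth``.

    Returns ``(translation_mm, rotation_deg)`` of the discrepancy map
    ``estimated^{-1} ∘ truth``; translation is the displacement of
    ``reference_point`` (typically the head center).
    """
    delta = np.linalg.inv(estimated.matrix) @ truth.matrix
    ref = np.asarray(reference_point, float)
    moved = delta[:3, :3] @ ref + delta[:3, 3]
    # rotation block may be non-orthonormal for affine estimates; polar-project
    u, _, vt = np.linalg.svd(delta[:3, :3])
    rot = u @ vt
    if np.linalg.det(rot) < 0:  # reflection guard (degenerate input)
        rot = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    ang = float(np.degrees(Rotation.from_matrix(rot).magnitude()))
    return float(np.linalg.norm(moved - ref)), ang


def resample_volume(
    moving: Volume,
    transform: AffineTransform,
    target: Volume,
    order: int = 1,
) -> Volume:
    """Resample ``moving`` onto ``target``'s grid under a moving->fixed map.

    Each target voxel's world position is pulled back through
    ``transform.inverse()`` and the moving image sampled there with
    trilinear (order=1) interpolation; out-of-volume positions get 0.
    """
    if target.data.size == 0:
        raise ValueError("target grid is empty")
    # Combined target-voxel -> moving-voxel map, all 4x4, single interpolation
    full = (
        np.linalg.inv(moving.affine)
        @ np.linalg.inv(transform.matrix)
        @ target.affine
    )
    from scipy import ndimage

    out = ndimage.affine_transform(
        moving.data,
        full[:3, :3],
        offset=full[:3, 3],
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    return Volume(out, target.affine.copy())


def apply_transform(volume_or_points, transform: AffineTransform, target_grid: Volume | None = None):
    """Apply a world transform to a Volume (resample) or to (N,3) points.

    Volumes require ``target_grid`` and are trilinearly resampled; points
    are mapped exactly via ``point_fixed = T(point_moving)``.
    """
    if isinstance(volume_or_points, Volume):
        if target_grid is None:
            raise ValueError("target_grid is required to resample a Volume")
        return resample_volume(volume_or_points, transform, target_grid)
    return transform.apply_points(np.asarray(volume_or_points, float))
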