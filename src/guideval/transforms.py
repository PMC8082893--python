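"""Rigid transforms (rotation + translation) in millimetre world coordinates.

A :class:`RigidTransform` is the currency of every alignment step: the ICP
result that maps an optical scan back onto the ground-truth bone, and the
planned-to-placed displacement matrix whose decomposition yields the eight
placement errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "compose", "inverse", "apply_transform"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t``.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Orthonormal matrix with determinant +1 (checked to 1e-9).
    translation : (3,) ndarray
        Translation in mm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("rigid transform contains non-finite entries")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major)."""
        M = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(rotation=M[:3, :3], translation=M[:3, 3])

    @classmethod
    def from_euler_xyz(cls, angles_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from fixed-axes X-Y-Z Euler angles in degrees."""
        R = Rotation.from_euler("xyz", np.asarray(angles_deg, float), degrees=True)
        return cls(rotation=R.as_matrix(), translation=np.asarray(translation, float))

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of points (or a single point)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(rotation=Rt, translation=-Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation angle (axis-angle magnitude), degrees."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    def is_identity(self, atol: float = _ORTHO_TOL) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= atol
            and np.abs(self.translation).max() <= atol
        )


def compose(first: RigidTransform, second: RigidTransform) -> RigidTransform:
    """Transform applying ``first`` and then ``second`` (i.e. ``second ∘ first``)."""
    return second.compose(first)


def inverse(T: RigidTransform) -> RigidTransform:
    return T.inverse()


def apply_transform(mesh, T: RigidTransform):
    """Return a transformed copy of a trimesh mesh (or bare (N,3) points)."""
    if isinstance(mesh, np.ndarray):
        return T.apply(mesh)
    out = mesh.copy()
    out.apply_transform(T.matrix)
    return out


def random_rigid_transform(
    rng: np.random.Generator,
    max_rotation_deg: float = 180.0,
    max_translation_mm: float = 10.0,
) -> RigidTransform:
    """Uniform-ish random rigid transform, for tests and simulation."""
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    angle = R.magnitude()
    if np.degrees(angle) > max_rotation_deg and angle > 0:
        R = Rotation.from_rotvec(R.as_rotvec() * np.radians(max_rotation_deg) / angle)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(rotation=R.as_matrix(), translation=t)
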