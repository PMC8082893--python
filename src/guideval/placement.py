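"""Planned-vs-placed reference-box comparison and the eight placement errors.

Each saw guide carries a 20 x 5 x 10 mm reference box whose pose defines
the guide's position. The displacement between the planned and the placed
box is expressed as a rigid transformation in the *planned box's local
frame* — local z along the bone's proximal direction, local y away from
the bone, local x completing the right-handed frame — and decomposed into
three translational errors (dx, dy, dz, mm), their root-sum-square total
dT, three rotational errors (phix, phiy, phiz, degrees, fixed-axes X-Y-Z
Euler decomposition) and their root-sum-square total dR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .registration import ICPParams, ICPResult, icp_register
from .transforms import RigidTransform

__all__ = [
    "BoxPose",
    "PlacementError",
    "placement_transform",
    "decompose_errors",
    "placement_error_pipeline",
]

DEFAULT_BOX_DIMS = (20.0, 5.0, 10.0)


@dataclass(frozen=True)
class BoxPose:
    """Pose of a reference box: centroid origin, orthonormal local frame.

    ``axes`` columns are the local x, y, z directions in world coordinates
    (right-handed, det +1). ``dims`` are the box edge lengths along the
    local axes, mm.
    """

    origin: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    dims: tuple = DEFAULT_BOX_DIMS

    def __post_init__(self):
        o = np.asarray(self.origin, float).reshape(3)
        A = np.asarray(self.axes, float).reshape(3, 3)
        if np.abs(A.T @ A - np.eye(3)).max() > 1e-6:
            raise ValueError("box axes must be orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("box axes must be right-handed (det +1)")
        d = tuple(float(x) for x in self.dims)
        if any(x <= 0 for x in d):
            raise ValueError("box dims must be positive")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", A)
        object.__setattr__(self, "dims", d)

    def transformed(self, T: RigidTransform) -> "BoxPose":
        """The pose after applying a world-frame rigid transform."""
        return BoxPose(
            origin=T.apply(self.origin), axes=T.rotation @ self.axes, dims=self.dims
        )

    def to_mesh(self) -> trimesh.Trimesh:
        """Axis-aligned-in-local-frame box mesh at this pose."""
        box = trimesh.creation.box(extents=self.dims)
        M = np.eye(4)
        M[:3, :3] = self.axes
        M[:3, 3] = self.origin
        box.apply_transform(M)
        return box

    def corners(self) -> np.ndarray:
        """(8, 3) world coordinates of the box corners."""
        half = np.array(self.dims) / 2.0
        signs = np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], float
        )
        return self.origin + (signs * half) @ self.axes.T


@dataclass(frozen=True)
class PlacementError:
    """The eight placement errors of one guide placement.

    Translations in mm along the planned box's local axes; rotations in
    degrees about those axes (fixed-axes X-Y-Z Euler). ``dT`` and ``dR``
    are the root-sum-squares of the components and are always >= 0;
    ``signed`` records whether the components retain their sign.
    """

    dx: float
    dy: float
    dz: float
    dT: float
    phix: float
    phiy: float
    phiz: float
    dR: float
    signed: bool = True
    geodesic_angle_deg: float = float("nan")

    def absolute(self) -> "PlacementError":
        """Drop component signs (dT/dR are unchanged: computed before)."""
        return PlacementError(
            dx=abs(self.dx), dy=abs(self.dy), dz=abs(self.dz), dT=self.dT,
            phix=abs(self.phix), phiy=abs(self.phiy), phiz=abs(self.phiz), dR=self.dR,
            signed=False, geodesic_angle_deg=self.geodesic_angle_deg,
        )

    def as_dict(self) -> dict:
        return {
            "dx": self.dx, "dy": self.dy, "dz": self.dz, "dT": self.dT,
            "phix": self.phix, "phiy": self.phiy, "phiz": self.phiz, "dR": self.dR,
        }


def placement_transform(planned: BoxPose, placed: BoxPose) -> RigidTransform:
    """Rigid transform T mapping the planned box onto the placed box,
    expressed in the planned box's local frame (rotation about the planned
    box centroid), so its translation components read directly as motion
    along the planned local axes."""
    R = planned.axes.T @ placed.axes
    t = planned.axes.T @ (placed.origin - planned.origin)
    return RigidTransform(rotation=R, translation=t)


def decompose_errors(T: RigidTransform, absolute: bool = False) -> PlacementError:
    """Decompose a local-frame placement transform into the eight errors.

    Rotations use the fixed-axes X-Y-Z Euler convention in degrees; near
    gimbal lock (|phiy| -> 90 deg) the decomposition is ill-conditioned
    and an error is raised — far outside the few-degree regime guide
    placement errors live in. The geodesic (axis-angle) rotation magnitude
    is carried along as a convention-free supplement.
    """
    import warnings

    rot = Rotation.from_matrix(T.rotation)
    with warnings.catch_warnings():
        # scipy warns at gimbal lock; we detect it below and raise instead
        warnings.simplefilter("ignore", UserWarning)
        phix, phiy, phiz = rot.as_euler("xyz", degrees=True)
    if abs(abs(phiy) - 90.0) < 1e-6:
        raise ValueError(
            "rotation is gimbal-locked (|phiy| ~ 90 deg); use a quaternion "
            "representation instead of Euler angles"
        )
    dx, dy, dz = T.translation
    dT = float(np.sqrt(dx * dx + dy * dy + dz * dz))
    dR = float(np.sqrt(phix * phix + phiy * phiy + phiz * phiz))
    err = PlacementError(
        dx=float(dx), dy=float(dy), dz=float(dz), dT=dT,
        phix=float(phix), phiy=float(phiy), phiz=float(phiz), dR=dR,
        signed=True, geodesic_angle_deg=float(np.degrees(rot.magnitude())),
    )
    return err.absolute() if absolute else err


def box_pose_from_mesh(
    box_mesh: trimesh.Trimesh,
    dims: tuple = DEFAULT_BOX_DIMS,
    reference: BoxPose | None = None,
) -> BoxPose:
    """Recover a BoxPose from a (possibly noisy) reference-box mesh.

    PCA of the vertices gives the frame up to axis permutation and sign;
    axes are assigned to x/y/z by matching the box edge lengths and, when a
    ``reference`` pose is given, signs/permutations are disambiguated by
    choosing the assignment closest to it (placement errors are far smaller
    than the 90/180-degree symmetries of a box).
    """
    verts = box_mesh.vertices.view(np.ndarray)
    centroid = verts.mean(axis=0)
    _, svals, Vt = np.linalg.svd(verts - centroid, full_matrices=False)
    # principal axes ordered by decreasing extent; dims order by decreasing length
    order = np.argsort(np.argsort(-np.asarray(dims)))  # rank of each local axis
    axes = np.empty((3, 3))
    for local_axis in range(3):
        axes[:, local_axis] = Vt[order[local_axis]]
    if np.linalg.det(axes) < 0:
        axes[:, 2] *= -1
    pose = BoxPose(origin=centroid, axes=axes, dims=dims)
    if reference is None:
        return pose
    best, best_angle = None, np.inf
    for fx, fy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        cand_axes = axes * np.array([fx, fy, fx * fy])  # keep det +1
        R = reference.axes.T @ cand_axes
        angle = Rotation.from_matrix(R).magnitude()
        if angle < best_angle:
            best_angle = angle
            best = cand_axes
    return BoxPose(origin=centroid, axes=best, dims=dims)


def placement_error_pipeline(
    ground_truth_bone: trimesh.Trimesh,
    optical_scan_bone: trimesh.Trimesh,
    optical_scan_box,
    planned,
    icp_params: ICPParams = ICPParams(),
    absolute: bool = False,
) -> tuple[PlacementError, ICPResult]:
    """Full placement-error measurement for one scanned guide placement.

    Registers the scanned bone (without guide) onto the ground-truth bone
    model, carries the recovered transform over to the scanned reference
    box, and decomposes planned-vs-placed box displacement into the eight
    errors. ``optical_scan_box`` may be a BoxPose in scan coordinates or a
    reference-box mesh (pose is then recovered by PCA). Non-convergence of
    the registration is reported through the returned ICPResult, never
    silently dropped.
    """
    planned_pose = planned.planned_box_pose if hasattr(planned, "planned_box_pose") else planned
    result = icp_register(optical_scan_bone, ground_truth_bone, icp_params)
    if isinstance(optical_scan_box, BoxPose):
        scan_pose = optical_scan_box
    else:
        scan_pose = box_pose_from_mesh(
            optical_scan_box,
            dims=planned_pose.dims,
            reference=planned_pose.transformed(result.transform.inverse()),
        )
    placed_pose = scan_pose.transformed(result.transform)
    T = placement_transform(planned_pose, placed_pose)
    return decompose_errors(T, absolute=absolute), result
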