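import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import guideval as gv
from guideval.placement import (
    BoxPose,
    box_pose_from_mesh,
    decompose_errors,
    placement_transform,
)
from guideval.transforms import RigidTransform, random_rigid_transform


def random_pose(rng, dims=(20.0, 5.0, 10.0)):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return BoxPose(origin=rng.normal(scale=30, size=3), axes=R.as_matrix(), dims=dims)


# ---------------------------------------------------------------------------
# placement_transform
# ---------------------------------------------------------------------------

def test_identical_poses_give_identity():
    pose = random_pose(np.random.default_rng(0))
    assert placement_transform(pose, pose).is_identity(atol=1e-12)


def test_pure_local_z_shift():
    planned = random_pose(np.random.default_rng(1))
    placed = BoxPose(
        origin=planned.origin + 3.0 * planned.axes[:, 2],
        axes=planned.axes, dims=planned.dims,
    )
    T = placement_transform(planned, placed)
    np.testing.assert_allclose(T.translation, [0, 0, 3], atol=1e-9)
    np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)


def test_transform_maps_planned_onto_placed():
    rng = np.random.default_rng(2)
    for _ in range(10):
        planned, placed = random_pose(rng), random_pose(rng)
        T = placement_transform(planned, placed)
        # re-express the local-frame transform in world coordinates
        origin = planned.origin + planned.axes @ T.translation
        axes = planned.axes @ T.rotation
        np.testing.assert_allclose(origin, placed.origin, atol=1e-9)
        np.testing.assert_allclose(axes, placed.axes, atol=1e-9)


def test_invalid_axes_rejected():
    with pytest.raises(ValueError, match="orthonormal"):
        BoxPose(origin=np.zeros(3), axes=np.eye(3) * 2)
    with pytest.raises(ValueError, match="right-handed"):
        BoxPose(origin=np.zeros(3), axes=np.diag([1.0, 1.0, -1.0]))


# ---------------------------------------------------------------------------
# decompose_errors
# ---------------------------------------------------------------------------

def test_identity_gives_all_zero_errors():
    err = decompose_errors(RigidTransform.identity())
    assert all(v == 0 for v in err.as_dict().values())


def test_pythagorean_translation():
    err = decompose_errors(RigidTransform(translation=[1, 2, 2]))
    assert err.dT == pytest.approx(3.0)
    assert err.dR == 0.0


def test_single_axis_rotation():
    T = RigidTransform.from_euler_xyz([0, 0, 2.0])
    err = decompose_errors(T)
    assert err.phiz == pytest.approx(2.0)
    assert err.phix == pytest.approx(0.0, abs=1e-12)
    assert err.phiy == pytest.approx(0.0, abs=1e-12)
    assert err.dR == pytest.approx(2.0)
    assert err.dT == 0.0


def test_euler_recomposition_reproduces_rotation():
    rng = np.random.default_rng(3)
    for _ in range(50):
        T = random_rigid_transform(rng, max_rotation_deg=30)
        err = decompose_errors(T)
        R = Rotation.from_euler(
            "xyz", [err.phix, err.phiy, err.phiz], degrees=True
        ).as_matrix()
        np.testing.assert_allclose(R, T.rotation, atol=1e-9)


def test_root_sum_square_identities_hold():
    rng = np.random.default_rng(4)
    for _ in range(200):
        T = random_rigid_transform(rng, max_rotation_deg=60)
        e = decompose_errors(T)
        assert e.dT == pytest.approx(np.sqrt(e.dx**2 + e.dy**2 + e.dz**2), abs=1e-9)
        assert e.dR == pytest.approx(
            np.sqrt(e.phix**2 + e.phiy**2 + e.phiz**2), abs=1e-9
        )


def test_totals_invariant_to_world_frame():
    rng = np.random.default_rng(5)
    planned, placed = random_pose(rng), random_pose(rng)
    base = decompose_errors(placement_transform(planned, placed))
    W = random_rigid_transform(rng)
    moved = decompose_errors(
        placement_transform(planned.transformed(W), placed.transformed(W))
    )
    assert moved.dT == pytest.approx(base.dT, abs=1e-9)
    assert moved.dR == pytest.approx(base.dR, abs=1e-9)


def test_small_angle_total_rotation_close_to_geodesic():
    """The Euler root-sum-square total rotation tracks the convention-free
    geodesic angle in the small-angle regime: within ~0.17% per degree of
    rotation (worst case over axes), i.e. < 0.9% at 5 degrees."""
    rng = np.random.default_rng(6)
    devs = []
    for _ in range(200):
        angle = rng.uniform(0.5, 5.0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        T = RigidTransform(
            rotation=Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
        )
        e = decompose_errors(T)
        dev = abs(e.dR - e.geodesic_angle_deg) / e.geodesic_angle_deg
        assert dev < 0.009
        devs.append(dev)
    assert np.mean(devs) < 0.005


def test_absolute_drops_signs_after_totals():
    T = RigidTransform.from_euler_xyz([-1, 0.5, -2], (-1, 2, -2))
    signed = decompose_errors(T)
    absolute = decompose_errors(T, absolute=True)
    assert absolute.dx == abs(signed.dx)
    assert absolute.phiz == abs(signed.phiz)
    assert absolute.dT == pytest.approx(signed.dT)
    assert absolute.dR == pytest.approx(signed.dR)
    assert not absolute.signed


def test_gimbal_lock_raises():
    T = RigidTransform.from_euler_xyz([10, 90, -5])
    with pytest.raises(ValueError, match="gimbal|quaternion"):
        decompose_errors(T)


# ---------------------------------------------------------------------------
# Box pose recovery from a mesh
# ---------------------------------------------------------------------------

def test_box_pose_recovered_from_its_own_mesh():
    rng = np.random.default_rng(7)
    pose = random_pose(rng)
    jiggle = BoxPose(
        origin=pose.origin + 0.3 * pose.axes[:, 0],
        axes=pose.axes @ Rotation.from_euler("xyz", [2, -1, 3], degrees=True).as_matrix(),
        dims=pose.dims,
    )
    recovered = box_pose_from_mesh(jiggle.to_mesh(), dims=pose.dims, reference=pose)
    np.testing.assert_allclose(recovered.origin, jiggle.origin, atol=1e-9)
    np.testing.assert_allclose(recovered.axes, jiggle.axes, atol=1e-6)


# ---------------------------------------------------------------------------
# End-to-end measurement pipeline
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def noiseless_scan(ground_truth):
    return gv.simulate_optical_scan(
        ground_truth,
        gv.ScanNoiseModel(vertex_jitter_sd=0.0, resample_density=0.0),
        np.random.default_rng(20),
    )


def test_pipeline_zero_noise_recovers_zero_error(ground_truth, guide_design, noiseless_scan):
    planned = guide_design.planned_box_pose
    scan_box = planned.transformed(noiseless_scan.true_offset)
    err, icp = gv.placement_error_pipeline(
        ground_truth, noiseless_scan.mesh, scan_box, guide_design
    )
    assert err.dT < 0.01
    assert err.dR < 0.01


def test_pipeline_recovers_injected_local_z_shift(ground_truth, guide_design, noiseless_scan):
    planned = guide_design.planned_box_pose
    shifted = BoxPose(
        origin=planned.origin + 2.0 * planned.axes[:, 2],
        axes=planned.axes, dims=planned.dims,
    )
    scan_box = shifted.transformed(noiseless_scan.true_offset)
    err, _ = gv.placement_error_pipeline(
        ground_truth, noiseless_scan.mesh, scan_box, guide_design
    )
    assert err.dz == pytest.approx(2.0, abs=0.02)
    for v in (err.dx, err.dy, err.phix, err.phiy, err.phiz):
        assert abs(v) < 0.02


def test_pipeline_recovers_mixed_injection(ground_truth, guide_design, noiseless_scan):
    planned = guide_design.planned_box_pose
    noise = RigidTransform.from_euler_xyz([0, 0, 2.0], (1.0, 0, 0))
    injected = BoxPose(
        origin=planned.origin + planned.axes @ noise.translation,
        axes=planned.axes @ noise.rotation, dims=planned.dims,
    )
    scan_box = injected.transformed(noiseless_scan.true_offset)
    err, _ = gv.placement_error_pipeline(
        ground_truth, noiseless_scan.mesh, scan_box, guide_design
    )
    assert err.dT == pytest.approx(1.0, abs=0.02)
    assert err.dR == pytest.approx(2.0, abs=0.02)
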