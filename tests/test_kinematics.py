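"""Rigid-pose estimation, gap filling, joint angles, events, normalization."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.transform import Rotation

from stepdown.kinematics import (GaitCycleEvents, detect_events, estimate_pose,
                                 fill_marker_gaps, fill_orientation_gaps,
                                 joint_angles, joint_rotation, spatiotemporal,
                                 time_normalize)

REF = np.array(
    [[0.06, 0.02, 0.01], [-0.04, 0.05, 0.025],
     [-0.025, -0.05, 0.03], [0.03, 0.005, 0.07]]
)


def rigid_markers(rotations, origins, ref=REF, noise=0.0, rng=None):
    R = rotations.as_matrix()
    out = np.einsum("tij,mj->tmi", R, ref) + origins[:, None, :]
    if noise > 0:
        out = out + rng.normal(0, noise, out.shape)
    return out


def random_rotations(n, seed=0):
    return Rotation.random(n, rng=np.random.default_rng(seed))


class TestPoseEstimation:
    def test_noiseless_cluster_recovered_exactly(self):
        rots = random_rotations(50, 1)
        orig = np.cumsum(np.random.default_rng(2).normal(0, 0.01, (50, 3)), axis=0)
        pose = estimate_pose(rigid_markers(rots, orig), REF)
        err = (Rotation.from_quat(pose.quat) * rots.inv()).magnitude()
        assert np.max(err) < 1e-9
        np.testing.assert_allclose(pose.origin, orig, atol=1e-12)
        assert np.max(pose.residual_rms) < 1e-12

    def test_mirrored_marker_set_rejected(self):
        mirrored = REF.copy()
        mirrored[:, 1] *= -1  # reflection, not achievable by rotation
        with pytest.raises(ValueError, match="mirrored"):
            estimate_pose(mirrored[None], REF)

    def test_collinear_cluster_rejected(self):
        line = np.array([[0.0, 0, 0], [0.01, 0, 0], [0.02, 0, 0], [0.03, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            estimate_pose(line[None], line)

    def test_noisy_residual_matches_procrustes_oracle(self):
        rng = np.random.default_rng(3)
        rots = random_rotations(20, 4)
        orig = rng.normal(0, 0.5, (20, 3))
        world = rigid_markers(rots, orig, noise=1e-3, rng=rng)
        pose = estimate_pose(world, REF)
        refc = REF - REF.mean(axis=0)
        for t in range(20):
            wc = world[t] - world[t].mean(axis=0)
            R_o, _ = orthogonal_procrustes(refc, wc)
            res_o = np.sqrt(np.mean(np.sum((wc - refc @ R_o) ** 2, axis=1)))
            assert pose.residual_rms[t] == pytest.approx(res_o, abs=1e-10)

    def test_quaternions_unit_norm_and_hemisphere_continuous(self):
        rots = random_rotations(100, 5)
        pose = estimate_pose(rigid_markers(rots, np.zeros((100, 3))), REF)
        norms = np.linalg.norm(pose.quat, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        dots = np.sum(pose.quat[1:] * pose.quat[:-1], axis=1)
        assert np.all(dots >= 0)


class TestGapFilling:
    def _pose_with_gap(self, rots, gap):
        markers = rigid_markers(rots, np.zeros((len(rots), 3)))
        markers[gap] = np.nan
        return estimate_pose(markers, REF)

    def test_identical_bounds_give_constant_fill(self):
        rot = Rotation.from_euler("y", [[30.0]] * 10, degrees=True)
        pose = self._pose_with_gap(rot, slice(3, 7))
        filled = fill_orientation_gaps(pose)
        err = (Rotation.from_quat(filled.quat) * rot.inv()).magnitude()
        assert np.max(err) < 1e-12

    def test_geodesic_midpoint_of_quarter_turn_is_45_degrees(self):
        angles = np.zeros(11)
        angles[-1] = 90.0
        rot = Rotation.from_euler("x", angles[:, None], degrees=True)
        pose = self._pose_with_gap(rot, slice(1, 10))
        filled = fill_orientation_gaps(pose)
        mid = Rotation.from_quat(filled.quat[5])
        want = Rotation.from_euler("x", 45.0, degrees=True)
        assert (mid * want.inv()).magnitude() < 1e-9

    def test_slerp_matches_fractional_rotation_power_oracle(self):
        """Slerp equals R1 (R1^T R2)^s for random orientation pairs."""
        rng = np.random.default_rng(6)
        pairs = random_rotations(20, 7)
        for k in range(0, 20, 2):
            r1, r2 = pairs[k], pairs[k + 1]
            seq = Rotation.concatenate(
                [r1] + [Rotation.identity()] * 9 + [r2])
            markers = rigid_markers(seq, np.zeros((11, 3)))
            markers[1:10] = np.nan
            filled = fill_orientation_gaps(estimate_pose(markers, REF))
            for i in range(1, 10):
                s = i / 10.0
                oracle = r1 * ((r1.inv() * r2) ** s)
                got = Rotation.from_quat(filled.quat[i])
                assert (got * oracle.inv()).magnitude() < 1e-9

    def test_boundary_gap_and_oversized_gap_raise(self):
        rot = random_rotations(30, 8)
        with pytest.raises(ValueError, match="boundary"):
            fill_orientation_gaps(self._pose_with_gap(rot, slice(0, 3)))
        with pytest.raises(ValueError, match="max_gap"):
            fill_orientation_gaps(self._pose_with_gap(rot, slice(2, 28)),
                                  max_gap=20)

    def test_missing_marker_reconstructed_through_rigid_pose(self):
        rng = np.random.default_rng(9)
        rots = random_rotations(40, 10)
        orig = rng.normal(0, 0.2, (40, 3))
        world = rigid_markers(rots, orig)
        truth = world.copy()
        world[10:20, 2] = np.nan  # one marker missing for 10 frames
        pose = estimate_pose(world, REF)
        assert pose.valid.all()  # 3 markers still solve the pose
        filled = fill_marker_gaps(world, pose, REF)
        assert np.nanmax(np.abs(filled - truth)) < 1e-9


class TestJointAngles:
    def _pose(self, rot):
        return estimate_pose(rigid_markers(rot, np.zeros((len(rot), 3))), REF)

    def test_identical_orientations_give_zero_angles(self):
        rot = random_rotations(20, 11)
        traj = joint_angles(self._pose(rot), self._pose(rot), fs=100.0)
        np.testing.assert_allclose(traj.angle_deg, 0.0, atol=1e-8)

    def test_constructed_flexion_has_negative_sign(self):
        """A 30-degree flexion built by the shared joint convention is
        reported as -30 degrees."""
        parent = random_rotations(5, 12)
        child = parent * joint_rotation(np.full(5, -30.0))
        traj = joint_angles(self._pose(parent), self._pose(child), fs=100.0)
        np.testing.assert_allclose(traj.angle_deg, -30.0, atol=1e-7)

    def test_decompose_recompose_round_trip(self):
        rng = np.random.default_rng(13)
        parent = random_rotations(50, 14)
        sagittal = rng.uniform(-60, 40, 50)
        child = parent * joint_rotation(sagittal)
        traj = joint_angles(self._pose(parent), self._pose(child), fs=100.0)
        np.testing.assert_allclose(traj.angle_deg, sagittal, atol=1e-7)
        recomposed = parent * joint_rotation(traj.angle_deg)
        err = (recomposed * child.inv()).magnitude()
        assert np.max(err) < 1e-9

    def test_velocity_matches_analytic_derivative(self):
        fs = 100.0
        t = np.arange(300) / fs
        ang = 20.0 * np.sin(2 * np.pi * 1.5 * t)
        parent = Rotation.identity(300)
        child = joint_rotation(ang)
        traj = joint_angles(self._pose(parent), self._pose(child), fs=fs)
        want = 20.0 * 2 * np.pi * 1.5 * np.cos(2 * np.pi * 1.5 * t)
        np.testing.assert_allclose(traj.velocity_degps[2:-2], want[2:-2],
                                   atol=0.5)

    def test_gimbal_proximity_flagged(self):
        parent = Rotation.identity(3)
        child = Rotation.from_euler("YXZ", [[10, 85, 5]] * 3, degrees=True)
        traj = joint_angles(self._pose(parent), self._pose(child), fs=100.0)
        assert traj.gimbal_flag.all()


class TestEventsAndNormalization:
    @staticmethod
    def synthetic_feet(fs=100.0):
        """Two feet with contacts at 0.5 s (upper), 1.0 s (lower), 1.5 s."""
        from stepdown.markers import _smoothstep

        t = np.arange(int(2.0 * fs)) / fs

        def foot(contact, x0, x1, z0, z1, toeoff):
            tau = np.clip((t - toeoff) / (contact - toeoff), 0, 1)
            s = _smoothstep(tau)
            x = x0 + (x1 - x0) * s
            z = z0 + (z1 - z0) * s + 0.03 * np.sin(np.pi * tau) ** 2
            return np.column_stack([x, np.zeros_like(t), z])

        left = foot(0.5, -0.55, 0.0, 0.12, 0.12, 0.15)
        right = foot(1.0, -0.55, 0.55, 0.12, 0.07, 0.55)
        # left foot's second swing to the lower level
        second = foot(1.5, 0.0, 1.1, 0.12, 0.07, 1.05)
        left[t > 1.0] = second[t > 1.0]
        return left, right, t

    def test_events_detected_and_ordered(self):
        left, right, t = self.synthetic_feet()
        ev = detect_events(left, right, fs=100.0)
        assert ev.hs_pre < ev.landing < ev.hs_next
        assert abs(ev.hs_pre - 50) <= 1
        assert abs(ev.landing - 100) <= 1
        assert abs(ev.hs_next - 150) <= 1

    def test_invalid_event_order_rejected(self):
        with pytest.raises(ValueError):
            GaitCycleEvents(10, 5, 20)

    def test_doubling_sampling_rate_scales_indices(self):
        left1, right1, _ = self.synthetic_feet(fs=100.0)
        left2, right2, _ = self.synthetic_feet(fs=200.0)
        e1 = detect_events(left1, right1, fs=100.0)
        e2 = detect_events(left2, right2, fs=200.0)
        for a, b in [(e1.hs_pre, e2.hs_pre), (e1.landing, e2.landing),
                     (e1.hs_next, e2.hs_next)]:
            assert abs(2 * a - b) <= 2  # same times within one sample

    def test_normalize_constant_signal(self):
        ev = GaitCycleEvents(10, 60, 140)
        out = time_normalize(np.full(200, 3.3), ev)
        assert out.shape == (101,)
        np.testing.assert_allclose(out, 3.3)

    def test_normalize_pins_landing_at_node_50(self):
        sig = np.zeros(200)
        sig[60] = 1.0
        ev = GaitCycleEvents(10, 60, 140)
        out = time_normalize(sig, ev)
        assert out[50] == 1.0

    def test_midway_landing_warp_is_identity_resampling(self):
        sig = np.sin(np.linspace(0, 4 * np.pi, 201))
        ev = GaitCycleEvents(0, 100, 200)
        out = time_normalize(sig, ev)
        want = np.interp(np.linspace(0, 200, 101), np.arange(201), sig)
        np.testing.assert_allclose(out, want, atol=1e-12)

    def test_warped_sinusoid_matches_analytic_resampling(self):
        t = np.arange(300)
        sig = np.sin(2 * np.pi * t / 90.0)
        ev = GaitCycleEvents(20, 80, 260)
        out = time_normalize(sig, ev)
        first = np.interp(np.linspace(20, 80, 51), t, sig)
        second = np.interp(np.linspace(80, 260, 51), t, sig)
        want = np.concatenate([first, second[1:]])
        np.testing.assert_allclose(out, want, atol=1e-10)


class TestSpatiotemporal:
    def test_planted_feet_give_constructed_step_length(self):
        T = 100
        left = np.tile([0.0, 0.0, 0.07], (T, 1))
        right = np.tile([0.54, 0.0, 0.07], (T, 1))
        pelvis = np.column_stack(
            [np.linspace(0, 1, T), np.zeros(T), np.full(T, 1.0)])
        ev = GaitCycleEvents(10, 50, 90)
        sl, _ = spatiotemporal(left, right, pelvis, ev, fs=100.0)
        assert sl == pytest.approx(0.54)

    def test_constant_speed_pelvis_recovered_exactly(self):
        T = 200
        t = np.arange(T) / 100.0
        pelvis = np.column_stack([1.1 * t, np.zeros(T), np.ones(T)])
        feet = np.zeros((T, 3))
        ev = GaitCycleEvents(20, 100, 180)
        _, v = spatiotemporal(feet, feet, pelvis, ev, fs=100.0)
        assert v == pytest.approx(1.1, abs=1e-3)

    def test_quintic_path_speed_matches_analytic_mean_derivative(self):
        T = 200
        t = np.arange(T) / 100.0
        x = 0.2 * t**5 - 0.5 * t**3 + 1.5 * t
        pelvis = np.column_stack([x, np.zeros(T), np.ones(T)])
        ev = GaitCycleEvents(20, 100, 180)
        _, v = spatiotemporal(np.zeros((T, 3)), np.zeros((T, 3)), pelvis, ev,
                              fs=100.0)
        tt = t[20:181]
        want = np.mean(1.0 * t[20:181] ** 4 * 0 + 0.2 * 5 * tt**4
                       - 0.5 * 3 * tt**2 + 1.5)
        assert v == pytest.approx(want, abs=1e-3)

    def test_missing_pelvis_rejected(self):
        pelvis = np.full((50, 3), np.nan)
        with pytest.raises(ValueError):
            spatiotemporal(np.zeros((50, 3)), np.zeros((50, 3)), pelvis,
                           GaitCycleEvents(5, 20, 40), fs=100.0)
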