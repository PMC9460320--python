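"""Quaternion algebra, rotation-matrix conversion, and gravity-referenced fusion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from swimforce import orientation as ori
from swimforce import simulate as sim

from conftest import random_unit_quaternions

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def unit_quats(draw_dim=4):
    return (
        hst.lists(hst.floats(-1, 1, allow_nan=False), min_size=4, max_size=4)
        .map(np.array)
        .filter(lambda q: np.linalg.norm(q) > 1e-3)
        .map(lambda q: q / np.linalg.norm(q))
    )


class TestQuaternionAlgebra:
    def test_identity_element(self):
        q = random_unit_quaternions(1, seed=1)[0]
        np.testing.assert_allclose(ori.quat_multiply(IDENTITY, q), q, atol=1e-15)
        np.testing.assert_allclose(ori.quat_multiply(q, IDENTITY), q, atol=1e-15)

    def test_conjugate_is_inverse(self):
        for q in random_unit_quaternions(20, seed=2):
            prod = ori.quat_multiply(q, ori.quat_conjugate(q))
            np.testing.assert_allclose(prod, IDENTITY, atol=1e-12)

    def test_ij_equals_k(self):
        # expanding the Hamilton product by hand: i ⊗ j = k
        i = np.array([0.0, 1.0, 0.0, 0.0])
        j = np.array([0.0, 0.0, 1.0, 0.0])
        k = np.array([0.0, 0.0, 0.0, 1.0])
        np.testing.assert_allclose(ori.quat_multiply(i, j), k, atol=1e-15)

    @given(unit_quats(), unit_quats())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_product_of_units_is_unit(self, a, b):
        assert abs(np.linalg.norm(ori.quat_multiply(a, b)) - 1.0) < 1e-9

    def test_normalize_rejects_zero(self):
        with pytest.raises(ValueError):
            ori.quat_normalize(np.zeros(4))


class TestRotationMatrix:
    def test_identity_quaternion(self):
        np.testing.assert_allclose(ori.quat_to_rotmat(IDENTITY), np.eye(3), atol=1e-15)

    def test_half_turn_about_x(self):
        q = np.array([0.0, 1.0, 0.0, 0.0])
        np.testing.assert_allclose(ori.quat_to_rotmat(q), np.diag([1.0, -1.0, -1.0]), atol=1e-15)

    def test_matches_quaternion_sandwich(self):
        """Columns must rotate the basis vectors exactly as q ⊗ (0,v) ⊗ q*."""
        for q in random_unit_quaternions(50, seed=3):
            R = ori.quat_to_rotmat(q)
            for v in np.eye(3):
                np.testing.assert_allclose(R @ v, ori.quat_rotate(q, v), atol=1e-12)

    def test_orthonormal_det_plus_one(self):
        for q in random_unit_quaternions(200, seed=4):
            R = ori.quat_to_rotmat(q)
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)
            assert abs(np.linalg.det(R) - 1.0) < 1e-9

    def test_rejects_non_unit(self):
        with pytest.raises(ValueError):
            ori.quat_to_rotmat(np.array([1.0, 1.0, 0.0, 0.0]))

    def test_sign_ambiguity(self):
        q = random_unit_quaternions(1, seed=5)[0]
        np.testing.assert_allclose(ori.quat_to_rotmat(q), ori.quat_to_rotmat(-q), atol=1e-14)


class TestZAxisYComponent:
    def test_aligned_sensor_is_zero(self):
        assert ori.z_axis_y_component(IDENTITY) == 0.0

    def test_quarter_roll_points_minus_y(self):
        # 90° roll about x sends the sensor z-axis to −Y
        c = math.cos(math.pi / 4)
        s = math.sin(math.pi / 4)
        assert ori.z_axis_y_component(np.array([c, s, 0.0, 0.0])) == pytest.approx(-1.0, abs=1e-15)

    def test_equals_rotmat_entry_for_1000_random_quats(self):
        for q in random_unit_quaternions(1000, seed=6):
            assert ori.z_axis_y_component(q) == ori.quat_to_rotmat(q)[1, 2]


class TestMadgwickUpdate:
    def test_equilibrium_at_identity(self):
        sample = ori.ImuSample(0.0, np.zeros(3), np.array([0.0, 0.0, ori.GRAVITY]))
        q = ori.madgwick_update(IDENTITY, sample, 0.005)
        np.testing.assert_allclose(q, IDENTITY, atol=1e-12)

    def test_static_tilt_convergence_monotone(self):
        """With zero gyro, the predicted gravity direction converges
        monotonically to the accelerometer direction, to within 0.1 deg."""
        angle = math.radians(25.0)
        accel = np.array([0.0, math.sin(angle), math.cos(angle)]) * ori.GRAVITY
        sample = ori.ImuSample(0.0, np.zeros(3), accel)
        q = IDENTITY.copy()
        q_target = ori.tilt_from_accel(accel)
        prev_err = ori.quat_angle(q, q_target)
        step = ori.DEFAULT_BETA * 0.005  # per-step correction magnitude
        for _ in range(6000):
            q = ori.madgwick_update(q, sample, 0.005)
            err = ori.quat_angle(q, q_target)
            # monotone down to the limit cycle of the constant-magnitude step
            assert err <= prev_err + 2 * step
            prev_err = err
        assert math.degrees(prev_err) < 0.1

    def test_pure_gyro_integration_angle(self):
        """beta = 0: constant rate about one axis integrates to ω·N·dt."""
        w = 1.3
        n, dt = 400, 0.005
        q = IDENTITY.copy()
        sample = ori.ImuSample(0.0, np.array([0.0, w, 0.0]), np.zeros(3))
        for _ in range(n):
            q = ori.madgwick_update(q, sample, dt, beta=0.0)
        expected = ori.quat_from_axis_angle([0, 1, 0], w * n * dt)
        # first-order integration: small commutation-free error only
        assert ori.quat_angle(q, expected) < 1e-3

    def test_rejects_bad_inputs(self):
        sample = ori.ImuSample(0.0, np.zeros(3), np.array([0.0, 0.0, 9.8]))
        with pytest.raises(ValueError):
            ori.madgwick_update(IDENTITY, sample, 0.0)
        # NaN is rejected at sample construction already
        with pytest.raises(ValueError):
            ori.ImuSample(0.0, np.zeros(3), np.array([np.nan, 0.0, 0.0]))
        bad = ori.ImuSample(0.0, np.zeros(3), np.zeros(3))
        object.__setattr__(bad, "accel", np.array([np.nan, 0.0, 0.0]))
        with pytest.raises(ValueError):
            ori.madgwick_update(IDENTITY, bad, 0.005)

    def test_returns_unit_norm(self):
        rng = np.random.default_rng(7)
        q = IDENTITY.copy()
        for _ in range(100):
            sample = ori.ImuSample(0.0, rng.normal(size=3), rng.normal(size=3) + [0, 0, 9.8])
            q = ori.madgwick_update(q, sample, 0.005)
            assert abs(np.linalg.norm(q) - 1.0) < 1e-9


class TestFuseStream:
    def test_static_stream_stays_at_identity(self):
        n = 200
        t = np.arange(n) / 200.0
        stream = ori.ImuStream(t, np.zeros((n, 3)), np.tile([0.0, 0.0, ori.GRAVITY], (n, 1)))
        qs = ori.fuse_stream(stream)
        for q in qs:
            assert ori.quat_angle(q, IDENTITY) < 1e-9

    def test_empty_stream(self):
        assert ori.fuse_stream([]).shape == (0, 4)

    def test_noise_free_rotation_recovery_within_one_degree(self):
        """A noise-free simulated stroke at a slow front-crawl pace is tracked
        to better than 1 degree throughout."""
        truth = sim.simulate_stroke(sim.StrokeParams(phase_duration=2.0))
        quiet = sim.NoiseSpec(gyro_sd=0, accel_sd=0, marker_sd=0, pressure_sd=0)
        imu = sim.synthesize_imu(truth, quiet)
        qs = ori.fuse_stream(imu, q_init="accel")
        errors = [ori.quat_angle(a, b) for a, b in zip(qs, truth.q)]
        assert math.degrees(max(errors)) < 1.0

    def test_all_outputs_unit_norm(self):
        truth = sim.simulate_stroke()
        imu = sim.synthesize_imu(truth, sim.NoiseSpec(seed=11))
        qs = ori.fuse_stream(imu)
        np.testing.assert_allclose(np.linalg.norm(qs, axis=1), 1.0, atol=1e-9)

    def test_rejects_timestamp_gap(self):
        t = np.arange(100) / 200.0
        t[50:] += 0.1  # dropped samples
        stream = ori.ImuStream(t, np.zeros((100, 3)), np.tile([0.0, 0.0, 9.8], (100, 1)))
        with pytest.raises(ValueError, match="gap at sample 50"):
            ori.fuse_stream(stream)


class TestTiltFromAccel:
    def test_recovers_pure_pitch(self):
        for phi in np.radians([-160.0, -90.0, -20.0, 0.0, 45.0]):
            q_true = ori.quat_from_axis_angle([1, 0, 0], phi)
            accel = ori.quat_rotate(ori.quat_conjugate(q_true), np.array([0.0, 0.0, ori.GRAVITY]))
            q = ori.tilt_from_accel(accel)
            assert ori.quat_angle(q, q_true) < 1e-6
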