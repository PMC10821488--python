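"""Kinematic reconstruction: bias correction, speeds, attitude split, paths."""

import numpy as np
import pytest

from wheelmotion.io import ImuStream, StreamValidationError, WheelchairGeometry
from wheelmotion.kinematics import (
    chair_speed,
    compute_kinematics,
    correct_gyro_offset,
    decompose_wheel_gyro,
    differentiate,
    reconstruct_path,
    wheel_speed,
    yaw_rate_from_frame,
)
from wheelmotion.simulate import NoiseModel, TrajectoryTruth, render_imu

GEO = WheelchairGeometry(wheel_diameter=0.6, track_width=0.56, sensor_side="right")


def _stream(gyro, accel=None, role="wheel"):
    gyro = np.atleast_2d(np.asarray(gyro, dtype=float))
    n = len(gyro)
    if accel is None:
        accel = np.tile([0.0, 0.0, 9.80665], (n, 1))
    return ImuStream(role, np.arange(n) / 50.0, gyro, accel)


def _truth(v, w):
    t = np.arange(len(v)) / 50.0
    return TrajectoryTruth(t, np.asarray(v, float), np.asarray(w, float), [])


class TestGyroOffset:
    def test_constant_bias_removed_exactly(self):
        bias = np.array([2.0, -1.0, 0.5])
        stream = _stream(np.tile(bias, (500, 1)))
        out = correct_gyro_offset(stream)
        assert np.abs(out.gyro.mean(axis=0)).max() < 1e-9
        np.testing.assert_array_equal(out.accel, stream.accel)

    def test_always_moving_returns_unchanged(self, caplog):
        gyro = np.tile([100.0, 5.0, 5.0], (500, 1))
        stream = _stream(gyro)
        with caplog.at_level("WARNING"):
            out = correct_gyro_offset(stream)
        assert out is stream
        assert "offset not corrected" in caplog.text

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        gyro = rng.normal([1.5, -0.7, 0.2], 0.3, size=(800, 3))
        once = correct_gyro_offset(_stream(gyro))
        twice = correct_gyro_offset(once)
        np.testing.assert_allclose(once.gyro, twice.gyro, atol=1e-12)

    def test_recovers_injected_bias_on_simulated_trial(self):
        # ~20% stationary time around a long movement bout
        n = 5000
        t = np.arange(n) / 50.0
        v = np.where((t > 20) & (t < 80), 1.0, 0.0) * np.clip(
            np.minimum(t - 20, 80 - t), 0, 1
        )
        wheel, _ = render_imu(
            _truth(v, np.zeros(n)), GEO, NoiseModel(0.5, 0.05, 0.0), seed=1
        )
        biased = ImuStream(
            "wheel", wheel.timestamps, wheel.gyro + 1.5, wheel.accel
        )
        corrected = correct_gyro_offset(biased)
        estimate = (biased.gyro - corrected.gyro).mean(axis=0)
        assert np.abs(estimate - 1.5).max() < 0.05


class TestSpeeds:
    def test_wheel_speed_closed_form(self):
        stream = _stream([[114.5916, 0.0, 0.0]])  # 2 rad/s
        np.testing.assert_allclose(wheel_speed(stream, GEO), [0.6], atol=1e-4)

    def test_wheel_speed_zero(self):
        assert wheel_speed(_stream([[0.0, 0.0, 0.0]]), GEO)[0] == 0.0

    def test_wheel_speed_noiseless_trapezoid(self):
        n = 1000
        t = np.arange(n) / 50.0
        v = np.clip(np.minimum(t - 2, 16 - t), 0, 1) * 0.9
        wheel, _ = render_imu(_truth(v, np.zeros(n)), GEO, NoiseModel.noiseless(), seed=0)
        assert np.abs(wheel_speed(wheel, GEO) - v).max() < 1e-6

    def test_chair_speed_straight(self):
        v = chair_speed(np.array([1.0]), np.array([0.0]), GEO)
        assert v[0] == pytest.approx(1.0)

    def test_chair_speed_turn_correction(self):
        # right-wheel sensor on the outside of a 0.5 rad/s left turn
        v = chair_speed(np.array([1.0]), np.array([28.6479]), GEO)
        assert v[0] == pytest.approx(0.860, abs=1e-4)

    def test_chair_speed_length_mismatch(self):
        with pytest.raises(StreamValidationError):
            chair_speed(np.ones(3), np.ones(4), GEO)

    def test_chair_speed_matches_truth_on_slalom(self):
        n = 1500
        t = np.arange(n) / 50.0
        v = np.clip(np.minimum(t - 2, 26 - t), 0, 1) * 1.0
        w = 25 * np.sin(2 * np.pi * 0.25 * t) * (v > 0)
        wheel, frame = render_imu(_truth(v, w), GEO, NoiseModel.noiseless(), seed=0)
        v_hat = chair_speed(wheel_speed(wheel, GEO), yaw_rate_from_frame(frame), GEO)
        assert np.abs(v_hat - v).max() < 1e-3


class TestFrameYaw:
    def test_identity_under_mounting(self):
        frame = _stream([[0.0, 0.0, 30.0]] * 10, role="frame")
        np.testing.assert_allclose(yaw_rate_from_frame(frame), 30.0)

    def test_missing_frame_errors(self):
        with pytest.raises(StreamValidationError, match="S1"):
            yaw_rate_from_frame(None)

    def test_pirouette_integrates_to_360(self):
        n = 600
        _, frame = render_imu(
            _truth(np.zeros(n), np.full(n, 30.0)), GEO, NoiseModel.noiseless(), seed=0
        )
        total = np.trapezoid(yaw_rate_from_frame(frame), frame.timestamps)
        assert total == pytest.approx(360.0, abs=1.0)


class TestAttitudeDecomposition:
    def test_at_rest_all_rates_zero(self):
        stream = _stream(np.zeros((300, 3)))
        roll, pitch, yaw, theta = decompose_wheel_gyro(stream)
        assert np.abs(np.r_[roll, pitch, yaw]).max() < 1e-9
        assert np.ptp(theta) < 1e-6

    def test_straight_push_roll_is_spin_yaw_small(self):
        n = 700
        t = np.arange(n) / 50.0
        v = np.clip(np.minimum(t - 2, 10 - t), 0, 1) * 1.0
        wheel, _ = render_imu(_truth(v, np.zeros(n)), GEO, NoiseModel.noiseless(), seed=0)
        roll, _, yaw, _ = decompose_wheel_gyro(wheel)
        np.testing.assert_allclose(roll, wheel.gyro[:, 0])
        assert np.sqrt(np.mean(yaw**2)) < 0.5

    def test_slalom_yaw_tracked(self):
        # 1 Hz yaw oscillation +/-20 deg/s at 1 m/s
        n = 1000
        t = np.arange(n) / 50.0
        v = np.clip(np.minimum(t - 2, 18 - t), 0, 1) * 1.0
        w = 20 * np.sin(2 * np.pi * 1.0 * t) * (v > 0)
        wheel, _ = render_imu(_truth(v, w), GEO, NoiseModel.noiseless(), seed=0)
        _, _, yaw, _ = decompose_wheel_gyro(wheel)
        assert np.sqrt(np.mean((yaw - w) ** 2)) < 2.0


class TestDifferentiate:
    def test_ramp(self):
        t = np.arange(500) / 50.0
        d = differentiate(0.2 * t, t)
        assert np.abs(d[50:-50] - 0.2).max() < 1e-6

    def test_constant(self):
        t = np.arange(100) / 50.0
        assert np.abs(differentiate(np.full(100, 3.3), t)).max() < 1e-9

    def test_sine_amplitude_within_filter_attenuation(self):
        t = np.arange(1000) / 50.0
        d = differentiate(np.sin(2 * np.pi * 1.0 * t), t)
        peak = np.abs(d[100:-100]).max()
        assert peak == pytest.approx(2 * np.pi, rel=0.02)

    def test_short_series_falls_back(self):
        t = np.arange(5) / 50.0
        d = differentiate(0.2 * t, t)
        np.testing.assert_allclose(d, 0.2, atol=1e-9)


class TestPath:
    def _kin(self, v, w):
        n = len(v)
        t = np.arange(n) / 50.0
        from wheelmotion.kinematics import KinematicSeries

        z = np.zeros(n)
        return KinematicSeries(t, np.asarray(v, float), z, np.asarray(w, float),
                               z, z, z, z, z, z, "S2")

    def test_straight_line(self):
        kin = self._kin(np.ones(501), np.zeros(501))
        path = reconstruct_path(kin)
        assert path.x[-1] == pytest.approx(10.0, abs=1e-9)
        assert abs(path.y[-1]) < 1e-9
        assert path.total_distance == pytest.approx(10.0, abs=1e-9)

    def test_closed_circle(self):
        n = 1001  # 20 s
        kin = self._kin(np.full(n, np.pi / 10), np.full(n, 18.0))
        path = reconstruct_path(kin)
        assert np.hypot(path.x[-1], path.y[-1]) < 1e-2
        assert path.heading[-1] == pytest.approx(360.0, abs=1e-9)

    def test_distance_invariant_to_reversal(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0.5, 0.2, 800)
        kin_fwd = self._kin(v, np.zeros(800))
        kin_rev = self._kin(-v, np.zeros(800))
        assert reconstruct_path(kin_fwd).total_distance == pytest.approx(
            reconstruct_path(kin_rev).total_distance
        )


class TestFullChainOracle:
    """Noiseless simulated trial: reconstruction matches ground truth."""

    def test_s2_oracle(self, noiseless_trial, noiseless_synced, geometry):
        wheel, frame = noiseless_synced
        kin = compute_kinematics(wheel, geometry, frame=frame, variant="S2")
        tt = noiseless_trial.truth
        assert np.sqrt(np.mean((kin.forward_speed - tt.speed) ** 2)) < 1e-3
        assert np.sqrt(np.mean((kin.yaw_rate - tt.yaw_rate) ** 2)) < 0.1

    def test_s1_oracle(self, noiseless_trial, geometry):
        kin = compute_kinematics(noiseless_trial.wheel, geometry, variant="S1")
        tt = noiseless_trial.truth
        assert np.sqrt(np.mean((kin.forward_speed - tt.speed) ** 2)) < 1e-2
        assert np.sqrt(np.mean((kin.yaw_rate - tt.yaw_rate) ** 2)) < 2.0

    def test_s1_s2_yaw_agree_under_noise(self, cohort, geometry):
        from wheelmotion.io import synchronize

        trial = cohort[0]
        wheel, frame = synchronize(trial.wheel, trial.frame)
        kin1 = compute_kinematics(wheel, geometry, frame=None, variant="S1")
        kin2 = compute_kinematics(wheel, geometry, frame=frame, variant="S2")
        r = np.corrcoef(kin1.yaw_rate, kin2.yaw_rate)[0, 1]
        assert r > 0.95

    def test_s2_requires_frame(self, noiseless_trial, geometry):
        with pytest.raises(StreamValidationError, match="frame"):
            compute_kinematics(noiseless_trial.wheel, geometry, variant="S2")
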