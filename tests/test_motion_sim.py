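"""Synthetic IMU streams, turntable trajectories and word waveforms."""

import numpy as np
import pytest
from scipy.signal import periodogram

from lipwave.fusion import DEG, rotation_from_attitude
from lipwave.motion_sim import (
    RigidTrajectory,
    SensorModel,
    make_ground_truth_sentence,
    make_turntable_trajectory,
    make_word_template,
    sample_word,
    simulate_imu_stream,
    static_trajectory,
)
from lipwave.segparam import dtw_distance
from lipwave.synthesis import segment_word


class TestImuSimulation:
    def test_rest_reads_unit_gravity(self):
        traj = static_trajectory(1.0)
        stream = simulate_imu_stream(traj, SensorModel(sigma_v=0.0, sigma_g=0.0))
        assert np.allclose(stream.accel, [0, 0, 1.0], atol=1e-12)
        assert np.allclose(stream.gyro, 0.0, atol=1e-9)
        assert np.allclose(np.linalg.norm(stream.accel, axis=1), 1.0)

    def test_pure_pitch_30_gravity_projection(self):
        traj = static_trajectory(0.5, theta=30.0)
        stream = simulate_imu_stream(traj, SensorModel(sigma_v=0.0, sigma_g=0.0))
        assert np.allclose(stream.accel, [-0.5, 0.0, np.sqrt(3) / 2], atol=1e-9)

    def test_output_clipped_to_sensor_range(self):
        traj = static_trajectory(0.5)
        traj.accel_b = traj.accel_b - 5.0  # drives |f| way past 2 g
        stream = simulate_imu_stream(traj, SensorModel(sigma_v=0.0, sigma_g=0.0))
        assert stream.accel.max() <= 2.0
        traj2 = make_turntable_trajectory(dwell_s=0.2, ramp_s=0.05)  # fast ramps
        stream2 = simulate_imu_stream(traj2, SensorModel(sigma_v=0.0, sigma_g=0.0))
        assert np.abs(stream2.gyro).max() <= 200.0

    def test_misalignment_rotates_readings(self, rng):
        from lipwave.motion_sim import random_misalignment

        r = random_misalignment(rng)
        traj = static_trajectory(0.5, theta=10.0, gamma=-5.0)
        plain = simulate_imu_stream(traj, SensorModel(sigma_v=0.0, sigma_g=0.0))
        rotated = simulate_imu_stream(
            traj, SensorModel(misalignment=r, sigma_v=0.0, sigma_g=0.0)
        )
        assert np.allclose(rotated.accel, plain.accel @ r.T, atol=1e-12)

    def test_non_orthonormal_misalignment_rejected(self):
        with pytest.raises(ValueError):
            SensorModel(misalignment=np.diag([1.0, 1.0, 2.0]))


class TestTurntable:
    def test_nine_plateaus_for_15_deg_steps(self):
        traj = make_turntable_trajectory(sweep=(-60, 60), step=15)
        assert traj.dwell_angles.size == 9
        assert np.allclose(traj.dwell_angles, np.arange(-60, 61, 15))

    def test_single_step_gives_two_plateaus(self):
        traj = make_turntable_trajectory(sweep=(-60, 60), step=120)
        assert traj.dwell_angles.size == 2

    def test_plateau_attitudes_match_commanded(self):
        traj = make_turntable_trajectory(axis="x", dwell_s=0.5)
        on = traj.dwell_mask
        held = np.unique(np.round(traj.gamma[on], 12))
        assert np.allclose(np.sort(held), traj.dwell_angles)

    def test_angular_velocity_consistent_with_attitude_derivative(self):
        traj = make_turntable_trajectory(dwell_s=0.5)
        mats = traj.attitude_matrices()
        dt = traj.ts
        # residual of dM/dt = -[w x] M at interior samples
        for i in range(1, len(traj) - 1, 37):
            dm = (mats[i + 1] - mats[i - 1]) / (2 * dt)
            from lipwave.fusion import skew

            resid = dm + skew(traj.omega_b[i] * DEG) @ mats[i]
            assert np.abs(resid).max() < 5e-3

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            make_turntable_trajectory(step=-1.0)


class TestWordTemplates:
    def test_seeded_determinism(self):
        a = make_word_template("hello", 100, seed=3)
        b = make_word_template("hello", 100, seed=3)
        assert np.array_equal(a.waveform, b.waveform)

    def test_distinct_words_have_positive_dtw_distance(self):
        a = make_word_template("alpha", 100, seed=0)
        b = make_word_template("beta", 100, seed=0)
        assert dtw_distance(a.waveform, b.waveform).normalized > 0

    def test_band_limited_below_8hz(self):
        tpl = make_word_template("word", 120, seed=1)
        for ch in range(4):
            f, p = periodogram(tpl.waveform[ch], fs=tpl.fs)
            assert p[f > 8.0].sum() < 0.01 * p.sum()

    def test_rest_margins_and_amplitude_cap(self):
        tpl = make_word_template("word", 90, seed=2)
        assert np.abs(tpl.waveform).max() <= 60.0
        assert np.abs(tpl.waveform[:, 0]).max() < 2.0
        assert np.abs(tpl.waveform[:, -1]).max() < 2.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_word_template("x", 40)


class TestWordSampling:
    def test_zero_sd_reproduces_template(self):
        tpl = make_word_template("word", 100, seed=0)
        samples = sample_word(tpl, n=3, length_sd=0.0, amp_sd=0.0)
        for s in samples:
            assert np.allclose(s.data, tpl.waveform)

    def test_sample_count(self):
        tpl = make_word_template("word", 80, seed=0)
        assert len(sample_word(tpl, n=20, seed=1)) == 20

    def test_length_variability_matches_requested_sd(self):
        """Monte-Carlo: SD/mean of lengths ~ length_sd within 10%."""
        tpl = make_word_template("word", 200, seed=0)
        lengths = np.array(
            [s.length for s in sample_word(tpl, n=1000, length_sd=0.15, amp_sd=0.0, seed=2)]
        )
        cv = lengths.std() / lengths.mean()
        assert cv == pytest.approx(0.15, rel=0.10)


class TestGroundTruthSentence:
    def test_zero_params_equal_plain_concatenation_smoothed(self, word_bank):
        from lipwave.synthesis import concatenate_words, smooth_transitions

        words = [reps[0] for reps in word_bank.values()]
        got = make_ground_truth_sentence(words, [(0.0, 0.0)] * len(words), 0.0)
        expected = smooth_transitions(concatenate_words(words))
        assert np.allclose(got.data, expected.data)

    def test_output_length_is_sum_of_retained_lengths(self, word_bank):
        words = [reps[0] for reps in word_bank.values()]
        params = [(0.2, 0.1), (0.1, 0.3), (0.0, 0.25)]
        got = make_ground_truth_sentence(words, params, 0.0)
        expected = sum(
            w.length - int(np.floor(r * w.length)) - int(np.floor(e * w.length))
            for w, (r, e) in zip(words, params)
        )
        assert got.length == expected

    def test_seeded_determinism(self, word_bank):
        words = [reps[0] for reps in word_bank.values()]
        params = [(0.1, 0.1)] * len(words)
        a = make_ground_truth_sentence(words, params, jitter_sd=0.2, seed=9)
        b = make_ground_truth_sentence(words, params, jitter_sd=0.2, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_constraint_violation_rejected(self, word_bank):
        words = [reps[0] for reps in word_bank.values()]
        with pytest.raises(ValueError):
            make_ground_truth_sentence(words, [(0.7, 0.5)] * len(words), 0.0)
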