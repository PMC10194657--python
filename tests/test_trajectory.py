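"""Madgwick orientation, ZUPT detection and direct–reverse integration."""

import numpy as np
import pytest

from stridekit import trajectory as tj
from stridekit.core_io import G, IMUSignal
from stridekit.event_detection import DetectorSignal
from stridekit.simulator import (
    NoiseModel,
    SimulationConfig,
    foot_pose_model,
    quat_rotate,
    simulate_recording,
)


def _static_imu(n, fs=100.0, tilt=None):
    acc = np.tile([0.0, 0.0, G], (n, 1))
    if tilt is not None:
        acc = np.tile(tilt, (n, 1))
    return IMUSignal(acc=acc, gyr=np.zeros((n, 3))), np.arange(n) / fs


class TestMadgwick:
    def test_static_orientation_is_constant(self):
        imu, t = _static_imu(1000)
        ori = tj.madgwick_orientation(imu, t, beta=0.1)
        # drift < 0.1 degree over 10 s
        dots = np.abs(np.sum(ori.q * ori.q[0], axis=1))
        ang = 2 * np.arccos(np.clip(dots, -1, 1))
        assert np.degrees(ang).max() < 0.1

    def test_pure_yaw_rotation_recovered(self):
        # 90° yaw at 0.5 rad/s with beta→0: gravity gives no yaw information,
        # so the gyro integration must carry it
        fs = 500.0
        dur = np.pi / 2 / 0.5
        n = int(dur * fs)
        t = np.arange(n + 1) / fs
        gyr = np.tile([0.0, 0.0, 0.5], (n + 1, 1))
        acc = np.tile([0.0, 0.0, G], (n + 1, 1))
        ori = tj.madgwick_orientation(IMUSignal(acc=acc, gyr=gyr), t, beta=0.0)
        qf = ori.q[-1]
        yaw = np.degrees(2 * np.arctan2(qf[3], qf[0]))
        assert yaw == pytest.approx(90.0, abs=0.5)

    def test_unit_norm_maintained(self, noisy_sim):
        rec, _ = noisy_sim
        ori = tj.madgwick_orientation(rec.imu_left, rec.t, beta=0.1)
        np.testing.assert_allclose(np.linalg.norm(ori.q, axis=1), 1.0, atol=1e-9)

    def test_negative_beta_rejected(self):
        imu, t = _static_imu(10)
        with pytest.raises(ValueError):
            tj.madgwick_orientation(imu, t, beta=-0.1)


class TestZupt:
    def _det(self, values, fs=100.0):
        v = np.asarray(values, dtype=float)
        return DetectorSignal(t=np.arange(len(v)) / fs, value=v, kind="ARE")

    def test_all_zero_detector_spans_trial(self):
        out = tj.detect_zupt_intervals(self._det(np.zeros(500)))
        assert len(out) == 1
        assert out[0].start == 0.0 and out[0].end == pytest.approx(4.99)
        assert out[0].mid == pytest.approx((out[0].start + out[0].end) / 2)

    def test_80ms_run_rejected(self):
        v = np.ones(300)
        v[100:108] = 0.0  # 80 ms below threshold
        assert tj.detect_zupt_intervals(self._det(v)) == []

    def test_simulated_gait_one_interval_per_stance(self, clean_sim, clean_result):
        rec, truth = clean_sim
        zupts = clean_result.left.zupts
        ics = np.array([e.t for e in truth.events if e.side == "left" and e.kind == "IC"])
        fcs = np.array([e.t for e in truth.events if e.side == "left" and e.kind == "FC"])
        hits = 0
        for ic in ics:
            nxt = fcs[fcs > ic]
            end = nxt[0] if len(nxt) else rec.t[-1]
            hits += any(ic <= z.mid <= end for z in zupts)
        assert hits == len(ics)


class TestGravityRemoval:
    def test_static_residual_is_zero(self):
        imu, t = _static_imu(200)
        q = np.tile([1.0, 0, 0, 0], (200, 1))
        a = tj.gravity_free_acceleration(imu, tj.OrientationSeries(t=t, q=q))
        assert np.linalg.norm(a, axis=1).max() < 1e-9

    def test_round_trip_through_body_frame(self):
        # map a known global acceleration into the body frame with a random
        # orientation and recover it
        rng = np.random.default_rng(2)
        n = 300
        t = np.arange(n) / 100.0
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        qs = np.tile(q, (n, 1))
        a_true = np.column_stack(
            [np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), 0.2 * np.ones(n)]
        )
        from stridekit.simulator import quat_rotate_inv

        acc_body = quat_rotate_inv(qs, a_true + [0, 0, G])
        a_rec = tj.gravity_free_acceleration(
            IMUSignal(acc=acc_body, gyr=np.zeros((n, 3))), tj.OrientationSeries(t=t, q=qs)
        )
        np.testing.assert_allclose(a_rec, a_true, atol=1e-9)

    def test_mean_residual_small_in_zupt_intervals(self, clean_sim, clean_result):
        rec, _ = clean_sim
        side = clean_result.left
        imu = rec.imu_left
        ori = tj.madgwick_orientation(imu, rec.t, beta=0.1)
        a = tj.gravity_free_acceleration(imu, ori)
        # the detector smears the dwell by half its 0.2 s window on each
        # side, so only the interior is genuinely still; the residual mean
        # reflects the orientation filter's tilt error (g·sinδ ≈ 0.08 m/s²
        # at its transient worst for beta = 0.1 with these swing dynamics)
        norms = []
        for z in side.zupts[1:12]:
            sel = (rec.t >= z.start + 0.1) & (rec.t <= z.end - 0.1)
            if sel.any():
                norms.append(np.linalg.norm(a[sel].mean(axis=0)))
        assert max(norms) < 0.1
        assert np.mean(norms) < 0.05


class TestDirectReverse:
    def _zupts(self, pairs):
        return [tj.ZuptInterval(start=a, end=b) for a, b in pairs]

    def test_zero_acceleration_zero_everything(self):
        t = np.arange(500) / 100.0
        a = np.zeros((500, 3))
        segs = tj.direct_reverse_integrate(t, a, self._zupts([(0.0, 0.4), (4.0, 4.6)]))
        assert len(segs) == 1
        assert np.abs(segs[0].velocity).max() == 0.0
        np.testing.assert_allclose(segs[0].displacement, 0.0)

    def test_velocity_exactly_zero_at_anchors(self, clean_result):
        for seg in clean_result.left.segments:
            np.testing.assert_array_equal(seg.velocity[0], 0.0)
            np.testing.assert_array_equal(seg.velocity[-1], 0.0)

    def test_one_metre_pulse_recovered(self):
        # symmetric accelerate–decelerate square pulse (±A for T each)
        # starting and ending at rest moves d = A·T²; A = 4, T = 0.5
        # gives exactly 1.00 m between the two still dwells
        fs = 100.0
        t = np.arange(0, 3.0, 1 / fs)
        a = np.zeros((len(t), 3))
        A, T = 4.0, 0.5
        a[(t >= 1.0) & (t < 1.0 + T), 0] = A
        a[(t >= 1.0 + T) & (t < 1.0 + 2 * T), 0] = -A
        segs = tj.direct_reverse_integrate(t, a, self._zupts([(0.0, 0.8), (2.2, 2.9)]))
        assert len(segs) == 1
        assert segs[0].displacement[0] == pytest.approx(1.00, abs=0.01)

    def test_constant_bias_partially_cancels(self):
        # adding a constant acceleration bias: the blended estimate beats
        # forward-only integration
        fs = 100.0
        t = np.arange(0, 3.0, 1 / fs)
        a = np.zeros((len(t), 3))
        A, T = 4.0, 0.5
        a[(t >= 1.0) & (t < 1.0 + T), 0] = A
        a[(t >= 1.0 + T) & (t < 1.0 + 2 * T), 0] = -A
        true_d = A * T**2  # 1.00 m
        bias = 0.2
        zupts = self._zupts([(0.0, 0.8), (2.2, 2.9)])
        segs = tj.direct_reverse_integrate(t, a + [bias, 0, 0], zupts)
        blended_err = abs(segs[0].displacement[0] - true_d)
        from scipy.integrate import cumulative_trapezoid, trapezoid

        i0 = np.argmin(np.abs(t - zupts[0].mid))
        i1 = np.argmin(np.abs(t - zupts[1].mid))
        vf = cumulative_trapezoid(a[i0 : i1 + 1, 0] + bias, t[i0 : i1 + 1], initial=0.0)
        fwd_err = abs(trapezoid(vf, t[i0 : i1 + 1]) - true_d)
        assert blended_err < fwd_err

    def test_fewer_than_two_anchors_no_output(self):
        t = np.arange(100) / 100.0
        assert tj.direct_reverse_integrate(t, np.zeros((100, 3)), self._zupts([(0, 0.5)])) == []


class TestStrideSpatial:
    def test_yaw_rotation_invariance(self, clean_sim, clean_result):
        # stride lengths are horizontal norms, so yawing the global frame by
        # 30° (rotating the gravity-free accelerations) leaves them unchanged
        rec, _ = clean_sim
        side = clean_result.left
        imu = rec.imu_left
        ori = tj.madgwick_orientation(imu, rec.t, beta=0.1)
        a = tj.gravity_free_acceleration(imu, ori)
        c, s = np.cos(np.radians(30)), np.sin(np.radians(30))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        segs1 = tj.direct_reverse_integrate(rec.t, a, side.zupts)
        segs2 = tj.direct_reverse_integrate(rec.t, a @ R.T, side.zupts)
        l1 = [np.linalg.norm(g.displacement[:2]) for g in segs1]
        l2 = [np.linalg.norm(g.displacement[:2]) for g in segs2]
        np.testing.assert_allclose(l1, l2, atol=1e-6)

    def test_velocity_is_length_over_duration(self, clean_result):
        for s in clean_result.valid_strides:
            assert s.velocity == pytest.approx(s.length / s.duration)

    def test_unmatched_stride_flagged_unmeasured(self):
        from stridekit.gait_assembly import Stride

        st = Stride(side="left", t_ic=0.0, t_fc=0.6, t_ic_next=1.0)
        out = tj.stride_spatial([], [st])
        assert not out[0].measured
        assert np.isnan(st.length)


class TestOptimizeBeta:
    def test_grid_minimum_returned(self):
        errs = {0.05: 3.0, 0.1: 1.0, 0.2: 2.0}
        assert tj.optimize_beta(lambda b: errs[b], [0.05, 0.1, 0.2]) == 0.1

    def test_single_point_grid(self):
        assert tj.optimize_beta(lambda b: 1.0, [0.3]) == 0.3

    def test_tie_breaks_to_smallest(self):
        assert tj.optimize_beta(lambda b: 1.0, [0.2, 0.05, 0.1]) == 0.05

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            tj.optimize_beta(lambda b: 1.0, [])
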