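"""Activity recognition, insole/IMU event detection, validation and fusion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stridekit import event_detection as ed
from stridekit.core_io import G, IMUSignal, PressureInsoleSignal
from stridekit.events import FC, IC, SOURCE_FUSED, SOURCE_IMU, SOURCE_PI, GaitEvent, check_alternation


def _t(n, fs=100.0):
    return np.arange(n) / fs


class TestActivity:
    def test_gravity_only_is_inactive(self):
        n = 1000
        acc = np.tile([0.0, 0.0, G], (n, 1))
        out = ed.detect_activity(acc, acc, acc, _t(n))
        assert out.intervals == []

    def test_lowerback_active_but_feet_quiet_is_inactive(self):
        n = 1000
        rng = np.random.default_rng(0)
        lb = np.tile([0.0, 0.0, G], (n, 1)) + rng.normal(0, 2.0, (n, 3))
        quiet = np.tile([0.0, 0.0, G], (n, 1))
        out = ed.detect_activity(lb, quiet, quiet, _t(n))
        assert out.intervals == []

    def test_simulated_bout_covered_within_one_window(self, clean_sim):
        rec, truth = clean_sim
        act = ed.detect_activity(rec.imu_lowerback.acc, rec.imu_left.acc, rec.imu_right.acc, rec.t)
        assert len(act.intervals) == len(truth.bout_boundaries)
        for (a, b), (ta, tb) in zip(act.intervals, truth.bout_boundaries):
            assert a <= ta + 1.0 and b >= tb - 1.0  # bout covered ±1 window
            assert a >= ta - 1.5 and b <= tb + 1.5

    def test_window_longer_than_recording_errors(self):
        n = 50
        acc = np.zeros((n, 3))
        with pytest.raises(ValueError):
            ed.detect_activity(acc, acc, acc, _t(n), window_s=10.0)


class TestPiEvents:
    def test_noise_free_events_match_truth_within_one_sample(self, clean_sim):
        rec, truth = clean_sim
        dt = rec.t[1] - rec.t[0]
        for side in ("left", "right"):
            events = ed.detect_events_pi(getattr(rec, f"pi_{side}"), rec.t, side)
            for kind in (IC, FC):
                det = [e.t for e in events if e.kind == kind]
                tru = [e.t for e in truth.events if e.side == side and e.kind == kind]
                for x in tru:
                    assert min(abs(d - x) for d in det) <= dt + 1e-9

    def test_isolated_blip_is_debounced(self):
        n = 500
        ch = np.zeros((n, 16))
        ch[100:102, 3] = 50.0  # 20 ms blip on a single channel
        pi = PressureInsoleSignal.default_layout(ch)
        assert ed.detect_events_pi(pi, _t(n), "left") == []

    def test_two_episodes_give_two_alternating_pairs(self):
        n = 1000
        ch = np.zeros((n, 16))
        ch[100:300, :] = 80.0
        ch[600:800, :] = 80.0
        pi = PressureInsoleSignal.default_layout(ch)
        events = ed.detect_events_pi(pi, _t(n), "left")
        assert [e.kind for e in events] == [IC, FC, IC, FC]

    def test_all_zero_stream_yields_no_events(self):
        pi = PressureInsoleSignal.default_layout(np.zeros((300, 16)))
        assert ed.detect_events_pi(pi, _t(300), "left") == []


class TestDetectors:
    def test_constant_spin_normalizes_to_one(self):
        n = 400
        gyr = np.tile([0.0, 0.0, 1.0], (n, 1))
        out = ed.angular_rate_energy(gyr, _t(n))
        np.testing.assert_allclose(out.value, 1.0)

    def test_zero_gyro_gives_zeros(self):
        out = ed.angular_rate_energy(np.zeros((300, 3)), _t(300))
        assert not out.value.any()

    def test_constant_acc_gives_zero_variance(self):
        acc = np.tile([0.0, 0.0, G], (400, 1))
        out = ed.moving_variance(acc, _t(400))
        np.testing.assert_allclose(out.value, 0.0, atol=1e-12)

    def test_step_change_peaks_at_one(self):
        acc = np.tile([0.0, 0.0, G], (400, 1))
        acc[200:, 2] += 5.0
        out = ed.moving_variance(acc, _t(400))
        assert out.value.max() == pytest.approx(1.0)
        assert 180 <= int(np.argmax(out.value)) <= 220

    def test_stance_dwells_fall_below_thresholds(self, clean_sim):
        rec, truth = clean_sim
        t = rec.t
        are = ed.angular_rate_energy(rec.imu_left.gyr, t)
        mv = ed.moving_variance(rec.imu_left.acc, t)
        ics = np.array([e.t for e in truth.events if e.side == "left" and e.kind == "IC"])
        fcs = np.array([e.t for e in truth.events if e.side == "left" and e.kind == "FC"])
        for ic in ics[:10]:
            nxt = fcs[fcs > ic]
            if not len(nxt):
                continue
            mid = 0.5 * (ic + nxt[0])
            sel = (t > mid - 0.05) & (t < mid + 0.05)
            assert are.value[sel].max() < ed.ARE_THRESHOLD
            assert mv.value[sel].max() < ed.MV_THRESHOLD

    def test_detectors_are_time_shift_equivariant(self):
        n = 600
        rng = np.random.default_rng(1)
        gyr = rng.normal(0, 1, (n, 3))
        a = ed.angular_rate_energy(gyr, _t(n))
        b = ed.angular_rate_energy(gyr, _t(n) + 100.0)
        np.testing.assert_array_equal(a.value, b.value)


class TestImuEvents:
    def test_static_recording_has_no_events(self):
        n = 1000
        imu = IMUSignal(acc=np.tile([0.0, 0.0, G], (n, 1)), gyr=np.zeros((n, 3)))
        act = ed.ActivityIntervals(intervals=[(0.0, 9.9)])
        assert ed.detect_events_imu(imu, act, _t(n), "left") == []

    def test_noise_free_ic_within_30ms_of_truth(self, clean_sim):
        rec, truth = clean_sim
        act = ed.detect_activity(rec.imu_lowerback.acc, rec.imu_left.acc, rec.imu_right.acc, rec.t)
        events = ed.detect_events_imu(rec.imu_left, act, rec.t, "left")
        det = [e.t for e in events if e.kind == IC]
        tru = [e.t for e in truth.events if e.side == "left" and e.kind == "IC"]
        errs = np.array([min(abs(d - x) for d in det) for x in tru])
        assert np.mean(errs <= 0.03) >= 0.95

    def test_events_alternate_on_any_input(self, noisy_sim):
        rec, _ = noisy_sim
        act = ed.detect_activity(rec.imu_lowerback.acc, rec.imu_left.acc, rec.imu_right.acc, rec.t)
        for side in ("left", "right"):
            events = ed.detect_events_imu(getattr(rec, f"imu_{side}"), act, rec.t, side)
            assert check_alternation(events)


def _det(values, fs=100.0, kind="ARE"):
    v = np.asarray(values, dtype=float)
    return ed.DetectorSignal(t=np.arange(len(v)) / fs, value=v, kind=kind)


class TestValidation:
    def _stance_pair(self, t_ic=1.0, t_fc=2.0):
        return [
            GaitEvent(t=t_ic, kind=IC, side="left", source=SOURCE_IMU),
            GaitEvent(t=t_fc, kind=FC, side="left", source=SOURCE_IMU),
        ]

    def _detector_with_dwell(self, dwell_s, start_s=1.2, n=300):
        v = np.ones(n)
        i0 = int(start_s * 100)
        v[i0 : i0 + int(dwell_s * 100)] = 0.0
        return _det(v)

    def test_150ms_dwell_on_both_detectors_kept(self):
        events = self._stance_pair()
        are = self._detector_with_dwell(0.15)
        mv = self._detector_with_dwell(0.15)
        assert ed.validate_imu_only_events(events, are, mv) == events

    def test_80ms_dwell_on_are_discarded(self):
        events = self._stance_pair()
        are = self._detector_with_dwell(0.08)
        mv = self._detector_with_dwell(0.15)
        assert ed.validate_imu_only_events(events, are, mv) == []

    def test_empty_input_empty_output(self):
        assert ed.validate_imu_only_events([], _det(np.ones(10)), _det(np.ones(10))) == []


class TestFusion:
    def test_matched_pair_takes_pi_time(self):
        pi = [GaitEvent(t=10.00, kind=IC, side="left", source=SOURCE_PI)]
        imu = [GaitEvent(t=10.10, kind=IC, side="left", source=SOURCE_IMU)]
        out = ed.fuse_events(pi, imu)
        assert len(out) == 1
        assert out[0].t == 10.00 and out[0].source == SOURCE_FUSED

    @pytest.mark.parametrize("delta,matched", [(0.249, True), (0.251, False)])
    def test_tolerance_boundary(self, delta, matched):
        pi = [GaitEvent(t=10.0, kind=IC, side="left", source=SOURCE_PI)]
        imu = [GaitEvent(t=10.0 + delta, kind=IC, side="left", source=SOURCE_IMU)]
        out = ed.fuse_events(pi, imu)
        sources = {e.source for e in out}
        if matched:
            assert sources == {SOURCE_FUSED}
        else:
            assert SOURCE_FUSED not in sources
            assert SOURCE_PI in sources  # unmatched insole event survives

    def test_pi_only_fc_kept_unchanged(self):
        pi = [GaitEvent(t=5.0, kind=FC, side="right", source=SOURCE_PI)]
        out = ed.fuse_events(pi, [])
        assert out == pi

    def test_all_pi_events_survive_fusion(self, clean_sim):
        rec, _ = clean_sim
        t = rec.t
        act = ed.detect_activity(rec.imu_lowerback.acc, rec.imu_left.acc, rec.imu_right.acc, t)
        pi_events = ed.detect_events_pi(rec.pi_left, t, "left")
        imu_events = ed.detect_events_imu(rec.imu_left, act, t, "left")
        out = ed.fuse_events(pi_events, imu_events)
        assert len(out) <= len(pi_events) + len(imu_events)
        out_times = {(e.t, e.kind) for e in out}
        assert all((e.t, e.kind) in out_times for e in pi_events)

    @given(
        pi_t=st.lists(st.floats(0, 50), max_size=8),
        imu_t=st.lists(st.floats(0, 50), max_size=8),
    )
    def test_fusion_output_alternates_and_is_bounded(self, pi_t, imu_t):
        pi = [GaitEvent(t=round(x, 3), kind=(IC if i % 2 == 0 else FC), side="left", source=SOURCE_PI)
              for i, x in enumerate(sorted(pi_t))]
        imu = [GaitEvent(t=round(x, 3), kind=(IC if i % 2 == 0 else FC), side="left", source=SOURCE_IMU)
               for i, x in enumerate(sorted(imu_t))]
        out = ed.fuse_events(pi, imu)
        assert len(out) <= len(pi) + len(imu)
        assert check_alternation(out)
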