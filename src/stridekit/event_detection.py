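"""Activity recognition and IC/FC gait-event detection from insoles and IMUs.

Three detector families feed the fused event stream:

* an activity recognizer flagging windows in which both the lower back and at
  least one foot accelerate enough to plausibly contain walking;
* a pressure-insole detector keying on activation/deactivation of anatomical
  sensor clusters (heel loads first at initial contact, toe unloads last at
  final contact);
* a foot-IMU detector locating mid-swing peaks of the sagittal angular rate
  and searching the surrounding minima for final and initial contacts.

Events from the two sensing routes are fused within a ±0.25 s tolerance; a
matched or insole-only event is trusted outright (the insole time is kept),
while IMU-only candidates must show a ≥100 ms still dwell on both the Angular
Rate Energy and Moving Variance detectors before being accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .core_io import IMUSignal, PressureInsoleSignal
from .events import (
    FC,
    IC,
    SOURCE_FUSED,
    SOURCE_IMU,
    SOURCE_PI,
    GaitEvent,
    enforce_alternation,
    sort_events,
)

# empirically chosen activity thresholds (m/s²) on the STD of total acceleration
LOWERBACK_STD_THRESHOLD = 0.7
FOOT_STD_THRESHOLD = 2.1

ARE_THRESHOLD = 0.5  # normalized units
MV_THRESHOLD = 0.005
MIN_DWELL_S = 0.1  # a stance must stay sub-threshold at least this long
FUSION_TOL_S = 0.25


@dataclass
class ActivityIntervals:
    """Sorted, non-overlapping [start, end] spans of dynamic activity."""

    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for a, b in self.intervals:
            if b <= a:
                raise ValueError("interval end must exceed start")
        for (a1, b1), (a2, b2) in zip(self.intervals, self.intervals[1:]):
            if a2 < b1:
                raise ValueError("intervals must be sorted and non-overlapping")

    def contains(self, t: float) -> bool:
        return any(a <= t <= b for a, b in self.intervals)

    def mask(self, t: np.ndarray) -> np.ndarray:
        m = np.zeros(len(t), dtype=bool)
        for a, b in self.intervals:
            m |= (t >= a) & (t <= b)
        return m


@dataclass
class DetectorSignal:
    """Normalized stillness detector output in [0, 1]."""

    t: np.ndarray
    value: np.ndarray
    kind: str  # ARE | MV


# ---------------------------------------------------------------------------
# activity recognition
# ---------------------------------------------------------------------------


def detect_activity(
    lowerback_acc: np.ndarray,
    foot_acc_left: np.ndarray,
    foot_acc_right: np.ndarray,
    t: np.ndarray,
    window_s: float = 1.0,
    merge_gap_s: float = 0.5,
) -> ActivityIntervals:
    """Windows where STD(‖acc_lowerback‖) > 0.7 m/s² AND either foot's
    STD(‖acc‖) > 2.1 m/s², using 1 s sliding windows with 50% overlap;
    adjacent or near-adjacent (≤ merge gap) active windows are merged."""
    fs = 1.0 / (t[1] - t[0])
    win = int(round(window_s * fs))
    if win > len(t):
        raise ValueError("window longer than recording")
    step = max(1, win // 2)

    norms = [np.linalg.norm(a, axis=1) for a in (lowerback_acc, foot_acc_left, foot_acc_right)]
    active_spans: list[tuple[float, float]] = []
    for i0 in range(0, len(t) - win + 1, step):
        sl = slice(i0, i0 + win)
        lb, fl, fr = (np.std(nrm[sl]) for nrm in norms)
        if lb > LOWERBACK_STD_THRESHOLD and (fl > FOOT_STD_THRESHOLD or fr > FOOT_STD_THRESHOLD):
            active_spans.append((t[i0], t[i0 + win - 1]))
    merged: list[tuple[float, float]] = []
    for a, b in active_spans:
        if merged and a - merged[-1][1] <= merge_gap_s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return ActivityIntervals(intervals=merged)


# ---------------------------------------------------------------------------
# pressure-insole events
# ---------------------------------------------------------------------------


def _debounce(active: np.ndarray, min_run: int) -> np.ndarray:
    """Remove active runs and fill inactive runs shorter than ``min_run``."""
    out = active.copy()
    for target in (True, False):
        i = 0
        n = len(out)
        while i < n:
            if out[i] == target:
                j = i
                while j < n and out[j] == target:
                    j += 1
                interior = i > 0 and j < n
                if j - i < min_run and (interior or target):
                    out[i:j] = not target
                i = j
            else:
                i += 1
    return out


def detect_events_pi(
    pi: PressureInsoleSignal,
    t: np.ndarray,
    side: str,
    k: float = 3.0,
    hysteresis_s: float = 0.05,
    min_region_channels: int = 2,
    rel_floor: float = 0.05,
) -> list[GaitEvent]:
    """IC/FC events from activation clusters of the 16 insole channels.

    Channels binarize at baseline + k·(baseline noise STD), with a relative
    floor of 5% of the channel's dynamic range (the deadband of a
    force-sensing resistor) and a 50 ms debounce; an anatomical region is
    active when at least two of its channels are; a contact episode is a
    contiguous span with any region active, yielding IC at the earliest
    activation onset and FC at the latest deactivation offset. An episode
    still active at the end of the recording emits its IC only (the foot
    never left the ground).
    """
    fs = 1.0 / (t[1] - t[0])
    hys = max(1, int(round(hysteresis_s * fs)))
    n = len(t)

    region_active: dict[str, np.ndarray] = {}
    for region in set(pi.region):
        cols = [j for j in range(16) if pi.region[j] == region]
        counts = np.zeros(n, dtype=int)
        for j in cols:
            ch = pi.channels[:, j]
            low = ch[ch <= np.percentile(ch, 50)]
            baseline = float(np.median(low))
            sigma = 1.4826 * float(np.median(np.abs(low - baseline)))
            span = float(np.percentile(ch, 99)) - baseline
            thresh = baseline + max(k * sigma, rel_floor * span)
            counts += _debounce(ch > thresh, hys)
        region_active[region] = _debounce(counts >= min_region_channels, hys)

    any_active = np.zeros(n, dtype=bool)
    for m in region_active.values():
        any_active |= m

    events: list[GaitEvent] = []
    i = 0
    while i < n:
        if any_active[i]:
            j = i
            while j < n and any_active[j]:
                j += 1
            events.append(GaitEvent(t=float(t[i]), kind=IC, side=side, source=SOURCE_PI))
            if j < n:  # deactivation observed before the trial ended
                events.append(GaitEvent(t=float(t[j - 1]), kind=FC, side=side, source=SOURCE_PI))
            i = j
        else:
            i += 1
    return events


# ---------------------------------------------------------------------------
# stillness detectors
# ---------------------------------------------------------------------------


def _normalize(value: np.ndarray, active_mask: np.ndarray | None) -> np.ndarray:
    ref = value[active_mask] if active_mask is not None and active_mask.any() else value
    vmax = float(np.max(ref)) if len(ref) else 0.0
    if vmax <= 0.0:
        return np.zeros_like(value)
    return np.clip(value / vmax, 0.0, 1.0)


def angular_rate_energy(
    gyr: np.ndarray,
    t: np.ndarray,
    window_s: float = 0.2,
    active_mask: np.ndarray | None = None,
) -> DetectorSignal:
    """Moving mean of ‖gyr‖² normalized to [0, 1] by its trial maximum
    (over the active portion when an activity mask is supplied)."""
    fs = 1.0 / (t[1] - t[0])
    win = max(1, int(round(window_s * fs)))
    energy = np.sum(gyr**2, axis=1)
    value = uniform_filter1d(energy, size=win, mode="nearest")
    return DetectorSignal(t=t, value=_normalize(value, active_mask), kind="ARE")


def moving_variance(
    acc: np.ndarray,
    t: np.ndarray,
    window_s: float = 0.2,
    active_mask: np.ndarray | None = None,
) -> DetectorSignal:
    """Moving variance of ‖acc‖ normalized to [0, 1] by its trial maximum."""
    fs = 1.0 / (t[1] - t[0])
    win = max(1, int(round(window_s * fs)))
    norm = np.linalg.norm(acc, axis=1)
    m1 = uniform_filter1d(norm, size=win, mode="nearest")
    m2 = uniform_filter1d(norm**2, size=win, mode="nearest")
    var = np.maximum(m2 - m1**2, 0.0)
    var[var < 1e-12 * np.max(m2)] = 0.0  # cancellation floor of m2 − m1²
    return DetectorSignal(t=t, value=_normalize(var, active_mask), kind="MV")


# ---------------------------------------------------------------------------
# foot-IMU events
# ---------------------------------------------------------------------------


def detect_events_imu(
    imu: IMUSignal,
    activity: ActivityIntervals,
    t: np.ndarray,
    side: str,
    sagittal_axis: int = 1,
    peak_height_frac: float = 0.3,
    min_peak_distance_s: float = 0.4,
) -> list[GaitEvent]:
    """IC/FC candidates from the sagittal angular rate within active intervals.

    Trusted mid-swings are the prominent positive peaks of the sagittal rate.
    The final contact of the preceding stance is the rate minimum in the
    half-window before each peak; the initial contact is the rate minimum in
    the half-window after it (windows bounded by the adjacent swing peaks).
    """
    fs = 1.0 / (t[1] - t[0])
    omega = imu.gyr[:, sagittal_axis]
    events: list[GaitEvent] = []

    for a, b in activity.intervals:
        i0 = int(np.searchsorted(t, a, side="left"))
        i1 = int(np.searchsorted(t, b, side="right"))
        seg = omega[i0:i1]
        if len(seg) < 3:
            continue
        height = peak_height_frac * float(np.max(np.abs(seg))) if np.any(seg != 0) else None
        if height is None or height <= 0:
            continue
        peaks, _ = find_peaks(seg, height=height, distance=max(1, int(min_peak_distance_s * fs)))
        if len(peaks) == 0:
            continue
        bounds = np.concatenate([[0], peaks, [len(seg) - 1]])
        for pi_, peak in enumerate(peaks):
            prev_b = bounds[pi_]
            next_b = bounds[pi_ + 2]
            # FC: minimum in the half-window leading into the swing peak
            lo = prev_b + (peak - prev_b) // 2
            if peak > lo:
                fc_idx = lo + int(np.argmin(seg[lo:peak]))
                events.append(
                    GaitEvent(t=float(t[i0 + fc_idx]), kind=FC, side=side, source=SOURCE_IMU)
                )
            # IC: minimum in the half-window after the swing peak
            hi = peak + max(1, (next_b - peak) // 2)
            if hi > peak + 1:
                ic_idx = peak + 1 + int(np.argmin(seg[peak + 1 : hi]))
                events.append(
                    GaitEvent(t=float(t[i0 + ic_idx]), kind=IC, side=side, source=SOURCE_IMU)
                )
    return enforce_alternation(events)


# ---------------------------------------------------------------------------
# validation of IMU-only stances and fusion
# ---------------------------------------------------------------------------


def _has_dwell(
    det: DetectorSignal, t_start: float, t_end: float, threshold: float, min_dwell_s: float
) -> bool:
    """True iff the detector stays below threshold for >= min_dwell_s
    contiguously somewhere within [t_start, t_end]."""
    sel = (det.t >= t_start) & (det.t <= t_end)
    if not sel.any():
        return False
    below = det.value[sel] < threshold
    dt = det.t[1] - det.t[0]
    run = 0
    best = 0
    for flag in below:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best * dt >= min_dwell_s


def validate_imu_only_events(
    events: list[GaitEvent],
    are: DetectorSignal,
    mv: DetectorSignal,
    are_threshold: float = ARE_THRESHOLD,
    mv_threshold: float = MV_THRESHOLD,
    min_dwell_s: float = MIN_DWELL_S,
) -> list[GaitEvent]:
    """Keep IMU-only IC,FC stance pairs only if both stillness detectors show
    a contiguous sub-threshold dwell of at least 100 ms within the stance."""
    evs = sort_events(events)
    keep: list[GaitEvent] = []
    i = 0
    while i < len(evs):
        ev = evs[i]
        nxt = evs[i + 1] if i + 1 < len(evs) else None
        if ev.kind == IC and nxt is not None and nxt.kind == FC:
            ok = _has_dwell(are, ev.t, nxt.t, are_threshold, min_dwell_s) and _has_dwell(
                mv, ev.t, nxt.t, mv_threshold, min_dwell_s
            )
            if ok:
                keep.extend([ev, nxt])
            i += 2
        else:
            keep.append(ev)  # unpaired boundary event passes through
            i += 1
    return keep


def fuse_events(
    pi_events: list[GaitEvent],
    imu_events: list[GaitEvent],
    tol_s: float = FUSION_TOL_S,
    are: DetectorSignal | None = None,
    mv: DetectorSignal | None = None,
) -> list[GaitEvent]:
    """Fuse insole and IMU events of one side.

    Greedy one-to-one nearest matching within ±tol_s per (side, kind); a
    matched pair becomes a FUSED event at the insole time. Insole-only
    events are kept as true events. IMU-only events pass the stance-dwell
    validation when detectors are supplied (and are kept as-is otherwise).
    The output is sorted with alternation restored by dropping the later of
    two consecutive same-kind events.
    """
    pi_events = sort_events(pi_events)
    imu_events = sort_events(imu_events)
    matched_imu: set[int] = set()
    fused: list[GaitEvent] = []

    for key in {(e.side, e.kind) for e in pi_events} | {(e.side, e.kind) for e in imu_events}:
        pis = [(i, e) for i, e in enumerate(pi_events) if (e.side, e.kind) == key]
        imus = [(j, e) for j, e in enumerate(imu_events) if (e.side, e.kind) == key]
        cand = [
            (abs(pe.t - ie.t), ie.t, pi_i, imu_j, pe)
            for pi_i, pe in pis
            for imu_j, ie in imus
            if abs(pe.t - ie.t) <= tol_s
        ]
        cand.sort()  # by distance, ties toward the earlier IMU event
        used_pi: set[int] = set()
        for _, _, pi_i, imu_j, pe in cand:
            if pi_i in used_pi or imu_j in matched_imu:
                continue
            used_pi.add(pi_i)
            matched_imu.add(imu_j)
            fused.append(GaitEvent(t=pe.t, kind=pe.kind, side=pe.side, source=SOURCE_FUSED))
        for pi_i, pe in pis:
            if pi_i not in used_pi:
                fused.append(pe)  # insole-only: a true event as-is

    leftovers = [e for j, e in enumerate(imu_events) if j not in matched_imu]
    if are is not None and mv is not None:
        leftovers = validate_imu_only_events(leftovers, are, mv)
    fused.extend(leftovers)

    by_side: list[GaitEvent] = []
    for side in ("left", "right"):
        by_side.extend(_restore_alternation([e for e in fused if e.side == side]))
    return sort_events(by_side)


def _restore_alternation(events: list[GaitEvent]) -> list[GaitEvent]:
    """Drop one of two consecutive same-kind events, preferring to keep the
    insole-backed (PI/FUSED) one; between equals, keep the earlier."""
    trusted = (SOURCE_PI, SOURCE_FUSED)
    out: list[GaitEvent] = []
    for ev in sort_events(events):
        if out and out[-1].kind == ev.kind:
            if ev.source in trusted and out[-1].source not in trusted:
                out[-1] = ev
            continue
        out.append(ev)
    return out
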