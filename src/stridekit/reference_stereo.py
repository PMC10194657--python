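"""Marker-based (stereophotogrammetric) reference gait pipeline.

Preprocessing gap-fills marker dropouts shorter than 0.5 s with a cubic
spline and applies a zero-lag 4th-order Butterworth low-pass at 7 Hz
(forward–backward, so effectively 8th order with no phase shift). Gait
events come from the anterior–posterior displacement of the heel and toe
markers relative to the pelvis-cluster centroid, projected onto the
instantaneous walking direction: heel-forward maxima mark initial contacts,
toe-backward minima mark final contacts, each refined to the nearest local
minimum of the marker's 3-D speed. Stride length and speed come from the
heel trajectory between consecutive ipsilateral initial contacts; stride
and bout selection reuse the wearable pipeline's criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, find_peaks

from .core_io import MARKER_GAP_LIMIT_S, MARKER_NAMES, PELVIS_NAMES, MarkerSet
from .events import FC, IC, SOURCE_MARKER, GaitEvent, enforce_alternation
from .gait_assembly import Stride

BUTTER_ORDER = 4
BUTTER_CUTOFF_HZ = 7.0
REFINE_WINDOW_S = 0.15


@dataclass
class FilteredMarkers:
    """Gap-filled, low-pass-filtered marker set with a fill audit trail."""

    markers: MarkerSet
    fill_log: list[dict]
    long_gap_flag: bool  # a foot-marker gap >= 0.5 s survived unfilled


def _gap_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _fill_and_filter(
    traj: np.ndarray, mask: np.ndarray, t: np.ndarray, name: str, fill_log: list[dict]
) -> tuple[np.ndarray, np.ndarray]:
    """Spline-fill short interior gaps, then zero-phase Butterworth each
    finite run. Returns (filtered trajectory, residual gap mask)."""
    fs = 1.0 / (t[1] - t[0])
    out = traj.copy()
    residual = mask.copy()
    good = ~mask
    if good.sum() >= 4:
        cs = [CubicSpline(t[good], out[good, ax]) for ax in range(3)]
        for i, j in _gap_runs(mask):
            interior = i > 0 and j < len(t)
            dur = (j - i) / fs
            if interior and dur < MARKER_GAP_LIMIT_S:
                for ax in range(3):
                    out[i:j, ax] = cs[ax](t[i:j])
                residual[i:j] = False
                fill_log.append({"marker": name, "start_s": float(t[i]), "duration_s": dur, "filled": True})
            else:
                fill_log.append({"marker": name, "start_s": float(t[i]), "duration_s": dur, "filled": False})
    b, a = butter(BUTTER_ORDER, BUTTER_CUTOFF_HZ / (fs / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    filtered = np.full_like(out, np.nan)
    for i, j in _gap_runs(~residual):  # finite runs
        if j - i > padlen:
            filtered[i:j] = filtfilt(b, a, out[i:j], axis=0)
        else:
            filtered[i:j] = out[i:j]
    filtered[residual] = np.nan
    return filtered, residual


def preprocess_markers(markers: MarkerSet, t: np.ndarray) -> FilteredMarkers:
    """Gap-fill (< 0.5 s, cubic spline) and low-pass all marker trajectories.

    Longer gaps stay masked; any such gap on a foot marker raises the
    recording-level flag but processing continues.
    """
    fill_log: list[dict] = []
    long_gap = False
    n = len(t)

    def process(name: str, traj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mask = markers.gap_mask.get(name, np.zeros(n, dtype=bool)) | np.isnan(traj).any(axis=1)
        return _fill_and_filter(traj, mask, t, name, fill_log)

    trajs = {}
    masks = {}
    fs = 1.0 / (t[1] - t[0])
    for name in MARKER_NAMES:
        trajs[name], masks[name] = process(name, markers.marker(name))
        if any((j - i) / fs > MARKER_GAP_LIMIT_S for i, j in _gap_runs(masks[name])):
            long_gap = True
    cluster = []
    for i, name in enumerate(PELVIS_NAMES):
        f, m = process(name, markers.pelvis_cluster[i])
        cluster.append(f)
        masks[name] = m

    filtered = MarkerSet(
        heel_left=trajs["heel_left"],
        toe_left=trajs["toe_left"],
        heel_right=trajs["heel_right"],
        toe_right=trajs["toe_right"],
        pelvis_cluster=np.stack(cluster),
        gap_mask=masks,
    )
    return FilteredMarkers(markers=filtered, fill_log=fill_log, long_gap_flag=long_gap)


# ---------------------------------------------------------------------------


def pelvis_center(markers: MarkerSet) -> np.ndarray:
    """Centroid of the 4-marker pelvis cluster."""
    if markers.pelvis_cluster is None or len(markers.pelvis_cluster) != 4:
        raise ValueError("pelvis cluster markers are required")
    return markers.pelvis_cluster.mean(axis=0)


def _walking_direction(pelvis: np.ndarray, t: np.ndarray, smooth_s: float = 0.5) -> np.ndarray:
    """Unit horizontal direction of pelvis progression (held through pauses)."""
    fs = 1.0 / (t[1] - t[0])
    vel = np.gradient(pelvis, t, axis=0)
    vel = uniform_filter1d(vel, size=max(3, int(smooth_s * fs)), axis=0, mode="nearest")
    horiz = vel[:, :2]
    speed = np.linalg.norm(horiz, axis=1)
    direction = np.zeros_like(horiz)
    last = np.array([1.0, 0.0])
    for i in range(len(t)):
        if speed[i] > 0.05:
            last = horiz[i] / speed[i]
        direction[i] = last
    return direction


def _refine_by_speed(
    cand_idx: int,
    traj: np.ndarray,
    t: np.ndarray,
    mode: str,
    window_s: float = REFINE_WINDOW_S,
    speed_frac: float = 0.1,
) -> int:
    """Refine a displacement-extremum candidate using the marker's 3-D speed.

    The marker is still on the ground on one side of the true event; within
    ±window_s of the candidate, samples below ``speed_frac`` of the local
    peak speed form the still plateau. For an initial contact (``mode
    'stop'``) the event is the plateau onset; for a final contact (``mode
    'start'``) it is the plateau end. Falls back to the plain speed minimum
    when no plateau exists.
    """
    fs = 1.0 / (t[1] - t[0])
    w = int(round(window_s * fs))
    lo = max(0, cand_idx - w)
    hi = min(len(t), cand_idx + w + 1)
    speed = np.linalg.norm(np.gradient(traj[lo:hi], t[lo:hi], axis=0), axis=1)
    vmax = np.nanmax(speed)
    if not np.isfinite(vmax) or vmax <= 0:
        return cand_idx
    below = speed < speed_frac * vmax
    if not below.any():
        return int(lo + np.nanargmin(speed))
    runs = _gap_runs(below)
    # the run nearest the candidate is the stance plateau
    rel = cand_idx - lo
    i, j = min(runs, key=lambda r: min(abs(r[0] - rel), abs(r[1] - 1 - rel)))
    return int(lo + (i if mode == "stop" else j - 1))


def detect_events_markers(
    heel: np.ndarray,
    toe: np.ndarray,
    pelvis: np.ndarray,
    t: np.ndarray,
    side: str,
    min_prominence_m: float = 0.05,
) -> list[GaitEvent]:
    """IC/FC events of one foot from marker kinematics.

    IC candidates: local maxima of the heel's anterior displacement from the
    pelvis centre along the walking direction. FC candidates: local minima
    of the toe's. Each candidate is refined to the nearest 3-D speed minimum
    of its marker within ±0.15 s; alternation is enforced.
    """
    if pelvis is None:
        raise ValueError("pelvis trajectory required for marker event detection")
    direction = _walking_direction(pelvis, t)
    heel_ap = np.einsum("ij,ij->i", (heel - pelvis)[:, :2], direction)
    toe_ap = np.einsum("ij,ij->i", (toe - pelvis)[:, :2], direction)

    heel_ap = np.nan_to_num(heel_ap, nan=0.0)
    toe_ap = np.nan_to_num(toe_ap, nan=0.0)
    ic_cand, _ = find_peaks(heel_ap, prominence=min_prominence_m)
    fc_cand, _ = find_peaks(-toe_ap, prominence=min_prominence_m)

    events = [
        GaitEvent(
            t=float(t[_refine_by_speed(i, heel, t, "stop", speed_frac=0.05)]),
            kind=IC, side=side, source=SOURCE_MARKER,
        )
        for i in ic_cand
    ]
    events += [
        GaitEvent(
            t=float(t[_refine_by_speed(i, toe, t, "start")]), kind=FC, side=side, source=SOURCE_MARKER
        )
        for i in fc_cand
    ]
    return enforce_alternation(events)


def stride_params_markers(
    heel: np.ndarray, t: np.ndarray, strides: list[Stride]
) -> list[Stride]:
    """Attach stride length/speed from heel positions at consecutive ICs
    (horizontal-plane distance; speed = length/duration)."""
    for s in strides:
        i0 = int(np.argmin(np.abs(t - s.t_ic)))
        i1 = int(np.argmin(np.abs(t - s.t_ic_next)))
        p0, p1 = heel[i0, :2], heel[i1, :2]
        if np.isnan(p0).any() or np.isnan(p1).any():
            s.length = float("nan")
            s.velocity = float("nan")
            continue
        s.length = float(np.linalg.norm(p1 - p0))
        s.velocity = s.length / s.duration if s.duration > 0 else float("nan")
    return strides
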