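"""Foot orientation, gravity removal and ZUPT-anchored stride displacement.

Orientation comes from a Madgwick complementary filter (gyro integration
with a gradient-descent accelerometer correction, one gain `beta`). The
Angular Rate Energy detector marks mid-stance zero-velocity (ZUPT) dwells;
the midpoint of each dwell is an integration anchor at which foot velocity
is assumed zero. Between consecutive anchors, gravity-free acceleration is
integrated both forward (zero initial velocity) and backward (zero final
velocity) and the two are blended with a linear weight, which forces the
velocity estimate to zero at both anchors and cancels constant drift to
first order. Stride length is the horizontal norm of the per-segment
displacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .core_io import G, IMUSignal
from .event_detection import ARE_THRESHOLD, MIN_DWELL_S, DetectorSignal
from .simulator import quat_rotate


@dataclass
class OrientationSeries:
    """Unit quaternions (wxyz, body→global) on the recording time base."""

    t: np.ndarray
    q: np.ndarray  # (n, 4)


@dataclass
class ZuptInterval:
    """A still dwell; ``mid`` is the integration anchor instant."""

    start: float
    end: float

    @property
    def mid(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class Segment:
    """Velocity/displacement between two consecutive ZUPT anchors."""

    t_start: float
    t_end: float
    t: np.ndarray
    velocity: np.ndarray  # (m, 3), exactly zero at both ends
    displacement: np.ndarray  # (3,)


@dataclass
class StrideSpatial:
    length: float  # m (NaN when unmeasured)
    velocity: float  # m/s
    displacement_3d: np.ndarray
    measured: bool


# ---------------------------------------------------------------------------
# Madgwick orientation filter (IMU variant)
# ---------------------------------------------------------------------------


def _q_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def tilt_from_accel(acc: np.ndarray) -> np.ndarray:
    """Shortest-arc quaternion aligning the measured gravity direction in the
    body frame with the global up axis (yaw left at zero)."""
    a = np.asarray(acc, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    a = a / norm
    z = np.array([0.0, 0.0, 1.0])
    # q rotates body vector a onto global z
    c = float(np.dot(a, z))
    if c > 1.0 - 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if c < -1.0 + 1e-12:
        return np.array([0.0, 1.0, 0.0, 0.0])  # 180° about x
    axis = np.cross(a, z)
    axis /= np.linalg.norm(axis)
    half = 0.5 * np.arccos(np.clip(c, -1.0, 1.0))
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def madgwick_orientation(
    imu: IMUSignal,
    t: np.ndarray,
    beta: float = 0.1,
    q0: Optional[np.ndarray] = None,
) -> OrientationSeries:
    """Standard Madgwick IMU update: gyro quaternion integration plus a
    gradient-descent accelerometer correction of magnitude ``beta`` (rad/s).

    ``q0`` defaults to the tilt implied by the first 0.5 s of accelerometer
    data (the sensor is assumed still at the start of a trial).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    n = len(t)
    q = np.empty((n, 4))
    if q0 is None:
        n0 = max(1, int(round(0.5 / (t[1] - t[0]))))
        q0 = tilt_from_accel(imu.acc[:n0].mean(axis=0))
    q[0] = q0 / np.linalg.norm(q0)

    acc = imu.acc
    gyr = imu.gyr
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        qw, qx, qy, qz = q[i - 1]
        gx, gy, gz = gyr[i]
        q_dot = 0.5 * _q_mul(q[i - 1], np.array([0.0, gx, gy, gz]))

        a = acc[i]
        a_norm = np.linalg.norm(a)
        if beta > 0 and a_norm > 0:
            ax, ay, az = a / a_norm
            # objective: rotate global gravity into body frame and compare
            f = np.array(
                [
                    2.0 * (qx * qz - qw * qy) - ax,
                    2.0 * (qw * qx + qy * qz) - ay,
                    2.0 * (0.5 - qx * qx - qy * qy) - az,
                ]
            )
            J = np.array(
                [
                    [-2.0 * qy, 2.0 * qz, -2.0 * qw, 2.0 * qx],
                    [2.0 * qx, 2.0 * qw, 2.0 * qz, 2.0 * qy],
                    [0.0, -4.0 * qx, -4.0 * qy, 0.0],
                ]
            )
            grad = J.T @ f
            gnorm = np.linalg.norm(grad)
            if gnorm > 0:
                q_dot = q_dot - beta * grad / gnorm
        qi = q[i - 1] + q_dot * dt
        q[i] = qi / np.linalg.norm(qi)
    return OrientationSeries(t=t, q=q)


# ---------------------------------------------------------------------------
# ZUPT and integration
# ---------------------------------------------------------------------------


def detect_zupt_intervals(
    are: DetectorSignal,
    threshold: float = ARE_THRESHOLD,
    min_dwell_s: float = MIN_DWELL_S,
) -> list[ZuptInterval]:
    """Maximal contiguous sub-threshold runs of the ARE detector lasting at
    least ``min_dwell_s``; the run midpoint is the integration anchor."""
    below = are.value < threshold
    t = are.t
    out: list[ZuptInterval] = []
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            start, end = float(t[i]), float(t[j - 1])
            if end - start >= min_dwell_s:
                out.append(ZuptInterval(start=start, end=end))
            i = j
        else:
            i += 1
    return out


def gravity_free_acceleration(imu: IMUSignal, orientation: OrientationSeries) -> np.ndarray:
    """Rotate body accelerations into the global frame and subtract gravity."""
    return quat_rotate(orientation.q, imu.acc) - np.array([0.0, 0.0, G])


def _linear_weight(s: np.ndarray) -> np.ndarray:
    return s


def _sigmoid_weight(s: np.ndarray, k: float = 10.0) -> np.ndarray:
    raw = 1.0 / (1.0 + np.exp(-k * (s - 0.5)))
    lo, hi = raw[0], raw[-1]
    return (raw - lo) / (hi - lo)


_WEIGHTS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": _linear_weight,
    "sigmoid": _sigmoid_weight,
}


def direct_reverse_integrate(
    t: np.ndarray,
    a_global: np.ndarray,
    zupts: Sequence[ZuptInterval],
    weighting: str = "linear",
) -> list[Segment]:
    """Velocity and displacement between consecutive ZUPT anchors.

    Forward velocity integrates trapezoidally from zero at the first anchor;
    reverse velocity integrates backward from zero at the second; the blend
    v = (1−s)·v_f + s·v_r (s the normalized time) is exactly zero at both
    anchors. Displacement is the trapezoidal integral of the blended
    velocity. Fewer than two anchors yield no segments.
    """
    if len(zupts) < 2:
        return []
    weight = _WEIGHTS[weighting]
    mids = [z.mid for z in zupts]
    idx = [int(np.argmin(np.abs(t - m))) for m in mids]
    segments: list[Segment] = []
    for i0, i1 in zip(idx, idx[1:]):
        if i1 <= i0 + 1:
            continue
        ts = t[i0 : i1 + 1]
        a = a_global[i0 : i1 + 1]
        v_f = cumulative_trapezoid(a, ts, axis=0, initial=0.0)
        s = (ts - ts[0]) / (ts[-1] - ts[0])
        w = weight(s)[:, None]
        v = v_f - w * v_f[-1]  # == (1-w)·v_f + w·(v_f − v_f[-1])
        disp = trapezoid(v, ts, axis=0)
        segments.append(
            Segment(t_start=float(ts[0]), t_end=float(ts[-1]), t=ts, velocity=v, displacement=disp)
        )
    return segments


def stride_spatial(
    segments: Sequence[Segment],
    strides: Sequence,
    use_3d: bool = False,
) -> list[StrideSpatial]:
    """Attach per-stride length and velocity from anchor-pair segments.

    A stride (IC to next ipsilateral IC) is matched to the segment that
    starts inside it and ends after its closing IC — mid-stance to
    mid-stance of the surrounding dwells. Strides without exactly one such
    segment are flagged unmeasured. Also writes ``length``/``velocity`` onto
    stride objects that carry those attributes.
    """
    out: list[StrideSpatial] = []
    for st in strides:
        cands = [
            seg
            for seg in segments
            if st.t_ic <= seg.t_start < st.t_ic_next < seg.t_end
        ]
        if len(cands) == 1:
            disp = cands[0].displacement
            length = float(np.linalg.norm(disp if use_3d else disp[:2]))
            duration = st.t_ic_next - st.t_ic
            vel = length / duration if duration > 0 else float("nan")
            sp = StrideSpatial(length=length, velocity=vel, displacement_3d=disp, measured=True)
        else:
            sp = StrideSpatial(
                length=float("nan"), velocity=float("nan"), displacement_3d=np.full(3, np.nan),
                measured=False,
            )
        if hasattr(st, "length"):
            st.length = sp.length
            st.velocity = sp.velocity
        out.append(sp)
    return out


def optimize_beta(error_fn: Callable[[float], float], beta_grid: Sequence[float]) -> float:
    """Exhaustive grid search for the Madgwick gain minimizing a stride-length
    error criterion; ties break toward the smallest beta."""
    grid = sorted(beta_grid)
    if not grid:
        raise ValueError("beta grid must not be empty")
    errors = [float(error_fn(b)) for b in grid]
    best = int(np.argmin(errors))  # argmin returns the first (smallest beta) on ties
    return grid[best]
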