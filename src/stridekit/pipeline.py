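"""End-to-end drivers: sensors → events → strides → bouts → DMOs.

`process_recording` runs the wearable chain on one synchronized recording;
`process_reference` runs the marker-based reference chain on the same
recording's stereophotogrammetric streams. Both end in the same stride/bout
selection rules, so their walking bouts can be matched and compared with
:mod:`stridekit.agreement_stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import event_detection as ed
from . import gait_assembly as ga
from . import reference_stereo as rs
from . import trajectory as tj
from .core_io import IMUSignal, Recording
from .events import GaitEvent


@dataclass
class SideResult:
    """Per-foot intermediate products of the wearable pipeline."""

    events: list[GaitEvent]
    strides: list[ga.Stride]
    zupts: list[tj.ZuptInterval]
    segments: list[tj.Segment]
    are: ed.DetectorSignal
    mv: ed.DetectorSignal
    gyr_bias: np.ndarray


@dataclass
class PipelineResult:
    bouts: list[ga.WalkingBout]
    left: SideResult
    right: SideResult
    activity: ed.ActivityIntervals

    @property
    def valid_strides(self) -> list[ga.Stride]:
        return [s for s in self.left.strides + self.right.strides if s.valid]


def _debias(imu: IMUSignal, bias: np.ndarray) -> IMUSignal:
    return IMUSignal(acc=imu.acc, gyr=imu.gyr - bias, mag=imu.mag)


def _process_side(
    rec: Recording,
    side: str,
    activity: ed.ActivityIntervals,
    beta: float,
    weighting: str,
    use_3d: bool,
) -> SideResult:
    imu: IMUSignal = getattr(rec, f"imu_{side}")
    pi = getattr(rec, f"pi_{side}")
    t = rec.t
    mask = activity.mask(t)

    are = ed.angular_rate_energy(imu.gyr, t, active_mask=mask)
    mv = ed.moving_variance(imu.acc, t, active_mask=mask)

    imu_events = ed.detect_events_imu(imu, activity, t, side)
    if pi is not None:
        pi_events = ed.detect_events_pi(pi, t, side)
        fused = ed.fuse_events(pi_events, imu_events, are=are, mv=mv)
    else:
        fused = ed.fuse_events([], imu_events, are=are, mv=mv)

    strides = ga.build_strides(fused)

    zupts = tj.detect_zupt_intervals(are)
    if zupts:
        zmask = np.zeros(len(t), dtype=bool)
        for z in zupts:
            zmask |= (t >= z.start) & (t <= z.end)
        # median resists the swing samples that leak into dwell edges
        bias = np.median(imu.gyr[zmask], axis=0)
    else:
        bias = np.zeros(3)
    imu_d = _debias(imu, bias)

    orientation = tj.madgwick_orientation(imu_d, t, beta=beta)
    a_glob = tj.gravity_free_acceleration(imu_d, orientation)
    segments = tj.direct_reverse_integrate(t, a_glob, zupts, weighting=weighting)
    tj.stride_spatial(segments, strides, use_3d=use_3d)
    ga.select_strides(strides)

    ds = getattr(rec, f"ds_{side}")
    for s in strides:
        ga.verify_with_distance_sensor(s, ds, t if ds is not None else None)

    return SideResult(
        events=fused, strides=strides, zupts=zupts, segments=segments, are=are, mv=mv,
        gyr_bias=np.asarray(bias),
    )


def process_recording(
    rec: Recording,
    beta: float = 0.1,
    weighting: str = "linear",
    use_3d: bool = False,
) -> PipelineResult:
    """Run the full wearable pipeline on a synchronized recording."""
    if rec.imu_lowerback is not None:
        activity = ed.detect_activity(
            rec.imu_lowerback.acc, rec.imu_left.acc, rec.imu_right.acc, rec.t
        )
    else:
        # without a lumbar unit the lower-back condition cannot be evaluated;
        # fall back to the foot criterion alone
        activity = ed.detect_activity(rec.imu_left.acc, rec.imu_left.acc, rec.imu_right.acc, rec.t)

    left = _process_side(rec, "left", activity, beta, weighting, use_3d)
    right = _process_side(rec, "right", activity, beta, weighting, use_3d)
    bouts = ga.build_walking_bouts(left.strides, right.strides)
    return PipelineResult(bouts=bouts, left=left, right=right, activity=activity)


def process_reference(rec: Recording) -> tuple[list[ga.WalkingBout], rs.FilteredMarkers]:
    """Run the marker-based reference pipeline on a recording's markers."""
    if rec.markers is None:
        raise ValueError("recording has no marker trajectories")
    filtered = rs.preprocess_markers(rec.markers, rec.t)
    m = filtered.markers
    pelvis = rs.pelvis_center(m)

    per_side: dict[str, list[ga.Stride]] = {}
    for side in ("left", "right"):
        heel = m.marker(f"heel_{side}")
        toe = m.marker(f"toe_{side}")
        events = rs.detect_events_markers(heel, toe, pelvis, rec.t, side)
        strides = ga.build_strides(events)
        rs.stride_params_markers(heel, rec.t, strides)
        ga.select_strides(strides)
        per_side[side] = strides
    bouts = ga.build_walking_bouts(per_side["left"], per_side["right"])
    return bouts, filtered


# ---------------------------------------------------------------------------
# Madgwick gain tuning against known stride lengths
# ---------------------------------------------------------------------------


def stride_length_mae(
    trials: Sequence[tuple[Recording, Sequence[float]]], beta: float
) -> float:
    """Mean absolute stride-length error of the pipeline at gain ``beta``
    over trials with known per-bout-ordered true stride lengths."""
    errs: list[float] = []
    for rec, true_lengths in trials:
        res = process_recording(rec, beta=beta)
        lengths = [s.length for s in sorted(res.valid_strides, key=lambda s: s.t_ic)]
        k = min(len(lengths), len(true_lengths))
        errs.extend(abs(lengths[i] - true_lengths[i]) for i in range(k))
    if not errs:
        return float("inf")
    return float(np.mean(errs))


def tune_beta(
    trials: Sequence[tuple[Recording, Sequence[float]]],
    beta_grid: Sequence[float] = (0.02, 0.05, 0.1, 0.2, 0.4),
) -> float:
    """Grid-optimize the Madgwick gain by minimizing stride-length MAE."""
    return tj.optimize_beta(lambda b: stride_length_mae(trials, b), beta_grid)
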