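"""Synthetic multi-sensor gait recordings with ground truth.

The generator produces the full sensor complement of one trial — foot and
lower-back IMUs, 16-channel pressure insoles, inter-leg distance sensors and
reflective markers — from an analytic foot-pose model, so that every stage of
the analysis pipeline can be exercised against known events and spatial
parameters.

The gait model alternates exact zero-velocity stance dwells with smooth
swings: horizontal progression follows a minimum-jerk profile, vertical lift
a sin² bump, and the foot pitches in the sagittal plane with an angular-rate
waveform whose prominent positive peak sits at mid-swing and whose negative
dips sit at toe-off and landing — the structure foot-worn event detectors
key on. Left and right feet are phase-shifted by half a gait cycle. Between
walking bouts the subject stands still, feet loaded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core_io import (
    G,
    DistanceSignal,
    IMUSignal,
    MarkerSet,
    PELVIS_NAMES,
    PressureInsoleSignal,
    Recording,
)
from .events import FC, IC, SOURCE_TRUTH, GaitEvent


@dataclass
class NoiseModel:
    """Additive sensor noise; defaults echo the reject ceilings of the
    deployed IMU fleet (accelerometer 3.31 mg, gyroscope 0.13 dps)."""

    acc_std: float = 3.31e-3 * G  # m/s² per axis
    gyr_std: float = 0.13 * math.pi / 180.0  # rad/s per axis
    gyr_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)  # rad/s, constant
    pi_noise_std: float = 0.0  # force units
    marker_noise_std: float = 0.0  # m

    def __post_init__(self) -> None:
        if min(self.acc_std, self.gyr_std, self.pi_noise_std, self.marker_noise_std) < 0:
            raise ValueError("noise magnitudes must be >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(acc_std=0.0, gyr_std=0.0, pi_noise_std=0.0, marker_noise_std=0.0)


@dataclass
class SimulationConfig:
    """Study-condition parameters of one simulated trial."""

    n_bouts: int = 3
    strides_per_bout: int = 10  # per side
    stride_duration: tuple[float, float] = (1.1, 0.0)  # mean, STD (s)
    stride_length: tuple[float, float] = (1.2, 0.0)  # mean, STD (m)
    stance_fraction: float = 0.6
    break_duration: float = 5.0  # standing between bouts (s)
    lead_s: float = 3.5  # standing before the first bout
    tail_s: float = 3.0  # standing after the last bout
    step_width: float = 0.1  # lateral inter-foot distance (m)
    foot_lift: float = 0.05  # swing vertical lift (m)
    foot_pitch_amplitude: float = 0.35  # rad, sagittal excursion during swing
    arc_deg_per_stride: float = 0.0  # optional curvilinear heading change
    pelvis_height: float = 1.0  # m
    fs: float = 100.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.2 <= self.stride_duration[0] <= 3.0):
            raise ValueError("mean stride duration must lie in [0.2, 3] s")
        if self.stride_length[0] < 0.15:
            raise ValueError("mean stride length must be >= 0.15 m")
        if not (0.0 < self.stance_fraction < 1.0):
            raise ValueError("stance_fraction must lie in (0, 1)")


@dataclass
class FootPose:
    """Sampled analytic foot pose with its exact kinematic derivatives."""

    t: np.ndarray
    pos: np.ndarray  # (n, 3) m, global frame
    q: np.ndarray  # (n, 4) wxyz unit quaternions, body→global
    vel: np.ndarray  # (n, 3) m/s, first derivative of pos
    acc_global: np.ndarray  # (n, 3) m/s², second derivative of pos
    omega_body: np.ndarray  # (n, 3) rad/s
    stance_mask: np.ndarray  # True where the foot is exactly still
    events: list[GaitEvent]
    stance_positions: np.ndarray  # (n_stance, 3) landing positions
    ic_times: np.ndarray
    fc_times: np.ndarray


@dataclass
class GroundTruth:
    """True events, per-stride parameters and bout boundaries of a trial."""

    events: list[GaitEvent]
    stride_durations: dict[str, np.ndarray]
    stride_lengths: dict[str, np.ndarray]
    bout_boundaries: list[tuple[float, float]]

    def n_strides(self, side: Optional[str] = None) -> int:
        if side is None:
            return sum(len(v) for v in self.stride_durations.values())
        return len(self.stride_durations[side])


# ---------------------------------------------------------------------------
# quaternion helpers (wxyz)
# ---------------------------------------------------------------------------


def quat_yaw_pitch(yaw: np.ndarray, pitch: np.ndarray) -> np.ndarray:
    """q = Rz(yaw) ∘ Ry(pitch) as wxyz quaternions."""
    cy, sy = np.cos(yaw / 2), np.sin(yaw / 2)
    cp, sp = np.cos(pitch / 2), np.sin(pitch / 2)
    return np.stack([cy * cp, -sy * sp, cy * sp, sy * cp], axis=-1)


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors v (body) into the global frame by unit quaternions q."""
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    qv = np.stack([x, y, z], axis=-1)
    t = 2.0 * np.cross(qv, v)
    return v + w[..., None] * t + np.cross(qv, t)


def quat_rotate_inv(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate global-frame vectors into the body frame."""
    qc = q.copy()
    qc[..., 1:] *= -1.0
    return quat_rotate(qc, v)


# ---------------------------------------------------------------------------
# swing profile
# ---------------------------------------------------------------------------


def _minjerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk progress s(τ) with first and second derivatives in τ."""
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    dds = 60 * tau - 180 * tau**2 + 120 * tau**3
    return s, ds, dds


@dataclass
class _SideSchedule:
    # per-swing: (t_fc, t_ic, p_from (3,), p_to (3,))
    swings: list[tuple[float, float, np.ndarray, np.ndarray]]
    ic_times: np.ndarray
    fc_times: np.ndarray
    stride_durations: np.ndarray  # per within-bout stride
    stride_lengths: np.ndarray
    stance_positions: np.ndarray


def _bout_starts(cfg: SimulationConfig) -> list[float]:
    """Deterministic, side-independent start time of each bout.

    A bout start is the instant of the leading foot's first toe-off. The
    nominal bout span (last landing of the trailing foot plus its terminal
    stance) is computed from the mean stride duration, with a 3-sigma margin
    when durations are stochastic so consecutive bouts cannot collide.
    """
    d_mu, d_sd = cfg.stride_duration
    n_sw = cfg.strides_per_bout + 1
    span = n_sw * d_mu + d_mu / 2.0 + cfg.stance_fraction * d_mu
    margin = 3.0 * d_sd * n_sw
    starts = [cfg.lead_s]
    for _ in range(cfg.n_bouts - 1):
        starts.append(starts[-1] + span + margin + cfg.break_duration)
    return starts


def _schedule_side(cfg: SimulationConfig, side: str, rng: np.random.Generator) -> _SideSchedule:
    """Lay out the stance/swing timeline and landing positions of one foot.

    Each bout contains ``strides_per_bout + 1`` swings per side: a stride is
    an IC-to-IC interval, so n strides need n+1 landings.
    """
    sf = cfg.stance_fraction
    d_mu, d_sd = cfg.stride_duration
    l_mu, l_sd = cfg.stride_length
    lat = cfg.step_width / 2.0 * (1.0 if side == "left" else -1.0)
    phase = 0.0 if side == "left" else d_mu / 2.0
    # natural stagger: the late-phased foot stands half a stride ahead, so
    # each swing leapfrogs the contralateral foot (one crossing per swing)
    x0 = 0.0 if side == "left" else l_mu / 2.0

    swings: list[tuple[float, float, np.ndarray, np.ndarray]] = []
    ic_times: list[float] = []
    fc_times: list[float] = []
    durations: list[float] = []
    lengths: list[float] = []
    stance_pos: list[np.ndarray] = [np.array([x0, lat, 0.0])]

    heading = 0.0
    pos = np.array([x0, lat, 0.0])
    n_swings = cfg.strides_per_bout + 1

    for t_bout in _bout_starts(cfg):
        bout_ics: list[float] = []
        t_fc = t_bout + phase
        for j in range(n_swings):
            d_j = max(0.25, d_mu + d_sd * rng.standard_normal()) if d_sd > 0 else d_mu
            l_j = max(0.16, l_mu + l_sd * rng.standard_normal()) if l_sd > 0 else l_mu
            swing = (1.0 - sf) * d_j
            if swing <= 0:
                raise ValueError("infeasible config: stance >= stride duration")
            t_ic = t_fc + swing
            if cfg.arc_deg_per_stride:
                heading += math.radians(cfg.arc_deg_per_stride)
            step = l_j * np.array([math.cos(heading), math.sin(heading), 0.0])
            new_pos = pos + step
            swings.append((t_fc, t_ic, pos.copy(), new_pos.copy()))
            fc_times.append(t_fc)
            ic_times.append(t_ic)
            bout_ics.append(t_ic)
            stance_pos.append(new_pos.copy())
            if j > 0:
                lengths.append(l_j)
            pos = new_pos
            t_fc = t_ic + sf * d_j  # next toe-off
        durations.extend(np.diff(bout_ics))
    return _SideSchedule(
        swings=swings,
        ic_times=np.array(ic_times),
        fc_times=np.array(fc_times),
        stride_durations=np.array(durations),
        stride_lengths=np.array(lengths),
        stance_positions=np.array(stance_pos),
    )


def foot_pose_model(cfg: SimulationConfig, side: str, rng: Optional[np.random.Generator] = None) -> FootPose:
    """Continuous foot pose of one side, sampled on the trial's 100 Hz grid.

    During every stance the position is exactly constant and the orientation
    flat (a true zero-velocity dwell); swings follow a minimum-jerk
    horizontal profile with a sin² vertical lift and a sagittal pitch whose
    angular rate peaks at mid-swing.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sched = _schedule_side(cfg, side, rng)
    t = _time_grid(cfg)
    n = len(t)
    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    acc = np.zeros((n, 3))
    pitch = np.zeros(n)
    omega = np.zeros((n, 3))
    stance = np.ones(n, dtype=bool)
    pos[:] = sched.swings[0][2]  # initial standing position

    for t_fc, t_ic, p0, p1 in sched.swings:
        w = t_ic - t_fc
        i0 = int(np.searchsorted(t, t_fc, side="left"))
        i1 = int(np.searchsorted(t, t_ic, side="right"))
        idx = slice(i0, i1)
        tau = (t[idx] - t_fc) / w
        tau = np.clip(tau, 0.0, 1.0)
        in_swing = (t[idx] > t_fc) & (t[idx] < t_ic)
        s, ds, dds = _minjerk(tau)
        dp = p1 - p0
        pos[idx] = p0 + np.outer(s, dp)
        pos[idx, 2] += cfg.foot_lift * np.sin(np.pi * tau) ** 2
        vel[idx] = np.outer(ds / w, dp)
        vel[idx, 2] += cfg.foot_lift * np.pi / w * np.sin(2.0 * np.pi * tau)
        acc[idx] = np.outer(dds / w**2, dp)
        acc[idx, 2] += (
            cfg.foot_lift * 2.0 * np.pi**2 / w**2 * np.cos(2.0 * np.pi * tau)
        )
        # sagittal pitch: θ(τ) = -A sin(2πτ), ω = dθ/dt
        A = cfg.foot_pitch_amplitude
        pitch[idx] = np.where(in_swing, -A * np.sin(2.0 * np.pi * tau), 0.0)
        omega[idx, 1] = np.where(in_swing, -A * 2.0 * np.pi / w * np.cos(2.0 * np.pi * tau), 0.0)
        stance[idx] = ~in_swing
        pos[i1:] = p1  # holds until the next swing overwrites

    heading = np.zeros(n)  # straight walking unless arc mode rotated steps
    if cfg.arc_deg_per_stride:
        # heading of the foot during each dwell equals the heading of its last step
        h = 0.0
        step_h = math.radians(cfg.arc_deg_per_stride)
        for t_fc, t_ic, p0, p1 in sched.swings:
            h += step_h
            heading[t >= t_fc] = h
    q = quat_yaw_pitch(heading, pitch)

    events = [GaitEvent(t=ti, kind=IC, side=side, source=SOURCE_TRUTH) for ti in sched.ic_times]
    events += [GaitEvent(t=tf, kind=FC, side=side, source=SOURCE_TRUTH) for tf in sched.fc_times]
    events.sort(key=lambda e: e.t)
    return FootPose(
        t=t,
        pos=pos,
        q=q,
        vel=vel,
        acc_global=acc,
        omega_body=omega,
        stance_mask=stance,
        events=events,
        stance_positions=sched.stance_positions,
        ic_times=sched.ic_times,
        fc_times=sched.fc_times,
    )


def _time_grid(cfg: SimulationConfig) -> np.ndarray:
    d_mu, d_sd = cfg.stride_duration
    n_sw = cfg.strides_per_bout + 1
    span = n_sw * d_mu + d_mu / 2.0 + cfg.stance_fraction * d_mu + 3.0 * d_sd * n_sw
    total = _bout_starts(cfg)[-1] + span + cfg.tail_s
    n = int(round(total * cfg.fs)) + 1
    return np.arange(n) / cfg.fs


# ---------------------------------------------------------------------------
# sensor synthesis
# ---------------------------------------------------------------------------


def synthesize_imu(pose: FootPose, noise: NoiseModel, rng: np.random.Generator) -> IMUSignal:
    """Ideal IMU from the pose: specific force in the body frame plus noise.

    accelerometer = R(q)ᵀ·(a_global + g·ẑ) + white noise;
    gyroscope = body rates + constant bias + white noise.
    """
    n = len(pose.t)
    g_vec = np.array([0.0, 0.0, G])
    acc_body = quat_rotate_inv(pose.q, pose.acc_global + g_vec)
    gyr = pose.omega_body + np.asarray(noise.gyr_bias)
    if noise.acc_std > 0:
        acc_body = acc_body + rng.normal(0.0, noise.acc_std, (n, 3))
    if noise.gyr_std > 0:
        gyr = gyr + rng.normal(0.0, noise.gyr_std, (n, 3))
    return IMUSignal(acc=acc_body, gyr=gyr)


def synthesize_imu_from_path(
    t: np.ndarray, path: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> IMUSignal:
    """IMU of a non-rotating segment (the lower back) from its path alone."""
    dt = t[1] - t[0]
    vel = np.gradient(path, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    acc = acc + np.array([0.0, 0.0, G])
    n = len(t)
    if noise.acc_std > 0:
        acc = acc + rng.normal(0.0, noise.acc_std, (n, 3))
    gyr = np.zeros((n, 3)) + np.asarray(noise.gyr_bias)
    if noise.gyr_std > 0:
        gyr = gyr + rng.normal(0.0, noise.gyr_std, (n, 3))
    return IMUSignal(acc=acc, gyr=gyr)


# contact roll-over pattern: fraction of stance at which each region loads
# and unloads (heel strikes first and unloads during roll-over; toe last off)
_REGION_WINDOWS = {
    "heel": (0.0, 0.40),
    "midfoot": (0.10, 0.55),
    "forefoot": (0.20, 0.90),
    "toe": (0.30, 1.00),
}
_PI_AMPLITUDE = 100.0  # arbitrary force units at full load


def synthesize_pi(
    pose: FootPose,
    noise: NoiseModel,
    rng: np.random.Generator,
    amplitude: float = _PI_AMPLITUDE,
) -> PressureInsoleSignal:
    """16-channel insole signal from the stance schedule of a pose.

    Heel-region channels load at IC and unload during mid-stance roll-over;
    forefoot/toe channels load after the heel and unload last at FC. Standing
    periods (before, between and after bouts) keep all regions loaded, so a
    landing that ends a bout stays in contact until the next toe-off.
    """
    t = pose.t
    n = len(t)
    channels = np.zeros((n, 16))
    pi = PressureInsoleSignal.default_layout(channels)

    # contact episodes: IC_i .. next FC (or end of trial for the last landing)
    fc_after = {}
    for t_ic in pose.ic_times:
        later = pose.fc_times[pose.fc_times > t_ic]
        fc_after[t_ic] = later[0] if len(later) else t[-1] + (t[1] - t[0])
    episodes = [(t_ic, fc_after[t_ic]) for t_ic in pose.ic_times]
    if len(pose.fc_times):
        episodes.insert(0, (t[0], pose.fc_times[0]))  # initial standing

    rise = 0.05  # s: FSR load/unload ramp, independent of stance duration
    for t_on, t_off in episodes:
        dur = t_off - t_on
        for j, region in enumerate(pi.region):
            f0, f1 = _REGION_WINDOWS[region]
            a, b = t_on + f0 * dur, t_on + f1 * dur
            idx = (t > a) & (t < b)
            # trapezoidal load: 50 ms ramps to full load, plateau between
            prof = np.minimum.reduce(
                [np.ones(idx.sum()), (t[idx] - a) / rise, (b - t[idx]) / rise]
            )
            channels[idx, j] = np.maximum(channels[idx, j], amplitude * prof)
    if noise.pi_noise_std > 0:
        channels += rng.normal(0.0, noise.pi_noise_std, channels.shape)
    np.maximum(channels, 0.0, out=channels)
    return replace(pi, channels=channels)


def synthesize_ds(
    pose_ipsi: FootPose, pose_contra: FootPose, fs_native: float = 50.0
) -> tuple[np.ndarray, DistanceSignal]:
    """Inter-leg distance seen from one ankle, at the native 50 Hz rate.

    The ranger points medially and reads the horizontal Euclidean inter-ankle
    distance, clamped at its 0.2 m limit: it dips into range once per
    contralateral swing pass and saturates otherwise. Returns (t_native, ds).
    """
    from .core_io import DS_RANGE_M

    t = pose_ipsi.t
    t50 = np.arange(0.0, t[-1] + 1e-12, 1.0 / fs_native)
    d_full = np.linalg.norm((pose_ipsi.pos - pose_contra.pos)[:, :2], axis=1)
    d50 = np.interp(t50, t, d_full)
    valid = d50 < DS_RANGE_M
    d50 = np.minimum(d50, DS_RANGE_M)
    return t50, DistanceSignal(d=d50, valid=valid, native_rate_hz=fs_native)


_HEEL_OFFSET = np.array([-0.08, 0.0, 0.02])  # body frame, m
_TOE_OFFSET = np.array([0.12, 0.0, 0.01])
_PELVIS_OFFSETS = np.array(
    [[0.06, 0.09, 0.0], [0.06, -0.09, 0.0], [-0.06, 0.09, 0.02], [-0.06, -0.09, 0.02]]
)


def pelvis_path(cfg: SimulationConfig, pose_l: FootPose, pose_r: FootPose) -> np.ndarray:
    """Smoothed mid-foot trajectory at pelvis height, with a vertical bob
    at step frequency during walking (what a lumbar IMU actually sees)."""
    from scipy.ndimage import uniform_filter1d

    t = pose_l.t
    fs = 1.0 / (t[1] - t[0])
    mid = 0.5 * (pose_l.pos + pose_r.pos)
    win = max(3, int(round(cfg.stride_duration[0] * fs)))
    center = uniform_filter1d(mid, size=win, axis=0, mode="nearest")
    center = center.copy()
    center[:, 2] = cfg.pelvis_height
    # walking envelope: both feet moving OR either foot in swing
    walking = ~(pose_l.stance_mask & pose_r.stance_mask)
    env = uniform_filter1d(walking.astype(float), size=win, mode="nearest")
    f_step = 2.0 / cfg.stride_duration[0]
    center[:, 2] += 0.02 * env * np.sin(2.0 * np.pi * f_step * t)
    return center


def synthesize_markers(
    pose_l: FootPose,
    pose_r: FootPose,
    pelvis: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
    gaps: Optional[dict[str, list[tuple[float, float]]]] = None,
) -> MarkerSet:
    """Heel/toe markers anchored to each foot pose plus a rigid pelvis cluster.

    ``gaps`` optionally injects occlusions: marker name → list of (start, end)
    times masked as missing (coordinates set to NaN).
    """
    t = pose_l.t

    def anchored(pose: FootPose, offset: np.ndarray) -> np.ndarray:
        return pose.pos + quat_rotate(pose.q, np.broadcast_to(offset, pose.pos.shape))

    trajs = {
        "heel_left": anchored(pose_l, _HEEL_OFFSET),
        "toe_left": anchored(pose_l, _TOE_OFFSET),
        "heel_right": anchored(pose_r, _HEEL_OFFSET),
        "toe_right": anchored(pose_r, _TOE_OFFSET),
    }
    cluster = np.stack([pelvis + off for off in _PELVIS_OFFSETS])
    if noise.marker_noise_std > 0:
        for k in trajs:
            trajs[k] = trajs[k] + rng.normal(0.0, noise.marker_noise_std, trajs[k].shape)
        cluster = cluster + rng.normal(0.0, noise.marker_noise_std, cluster.shape)

    gap_mask: dict[str, np.ndarray] = {}
    names = ("heel_left", "toe_left", "heel_right", "toe_right") + PELVIS_NAMES
    for name in names:
        gap_mask[name] = np.zeros(len(t), dtype=bool)
    if gaps:
        for name, spans in gaps.items():
            for a, b in spans:
                gap_mask[name] |= (t >= a) & (t <= b)
            arr = cluster[PELVIS_NAMES.index(name)] if name in PELVIS_NAMES else trajs[name]
            arr[gap_mask[name]] = np.nan

    return MarkerSet(
        heel_left=trajs["heel_left"],
        toe_left=trajs["toe_left"],
        heel_right=trajs["heel_right"],
        toe_right=trajs["toe_right"],
        pelvis_cluster=cluster,
        gap_mask=gap_mask,
    )


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------


def simulate_recording(
    cfg: SimulationConfig,
    marker_gaps: Optional[dict[str, list[tuple[float, float]]]] = None,
) -> tuple[Recording, GroundTruth]:
    """Assemble a complete synchronized trial and its ground truth.

    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    pose_l = foot_pose_model(cfg, "left", rng)
    pose_r = foot_pose_model(cfg, "right", rng)
    t = pose_l.t

    imu_l = synthesize_imu(pose_l, cfg.noise, rng)
    imu_r = synthesize_imu(pose_r, cfg.noise, rng)
    pelvis = pelvis_path(cfg, pose_l, pose_r)
    imu_lb = synthesize_imu_from_path(t, pelvis, cfg.noise, rng)
    pi_l = synthesize_pi(pose_l, cfg.noise, rng)
    pi_r = synthesize_pi(pose_r, cfg.noise, rng)

    t50, ds_l_native = synthesize_ds(pose_l, pose_r)
    _, ds_r_native = synthesize_ds(pose_r, pose_l)

    def ds_to_grid(ds: DistanceSignal) -> DistanceSignal:
        d = np.interp(t, t50, ds.d)
        idx = np.clip(np.searchsorted(t50, t), 0, len(t50) - 1)
        left = np.clip(idx - 1, 0, len(t50) - 1)
        nearer = np.where(np.abs(t50[idx] - t) <= np.abs(t - t50[left]), idx, left)
        return DistanceSignal(d=d, valid=ds.valid[nearer], native_rate_hz=ds.native_rate_hz)

    markers = synthesize_markers(pose_l, pose_r, pelvis, cfg.noise, rng, gaps=marker_gaps)

    rec = Recording(
        recording_id=f"sim-{cfg.seed}",
        fs=cfg.fs,
        t=t,
        imu_left=imu_l,
        imu_right=imu_r,
        imu_lowerback=imu_lb,
        pi_left=pi_l,
        pi_right=pi_r,
        ds_left=ds_to_grid(ds_l_native),
        ds_right=ds_to_grid(ds_r_native),
        markers=markers,
        meta={"simulated": True, "seed": cfg.seed},
    )

    events = sorted(pose_l.events + pose_r.events, key=lambda e: e.t)
    n_sw = cfg.strides_per_bout + 1
    bounds: list[tuple[float, float]] = []
    for b in range(cfg.n_bouts):
        # bout spans from its earliest toe-off to its last landing (either side)
        fc_first = min(pose_l.fc_times[b * n_sw], pose_r.fc_times[b * n_sw])
        ic_last = max(pose_l.ic_times[(b + 1) * n_sw - 1], pose_r.ic_times[(b + 1) * n_sw - 1])
        bounds.append((float(fc_first), float(ic_last)))

    truth = GroundTruth(
        events=events,
        stride_durations={
            "left": _per_bout_stride_durations(pose_l, cfg),
            "right": _per_bout_stride_durations(pose_r, cfg),
        },
        stride_lengths={
            "left": _per_bout_stride_lengths(pose_l, cfg),
            "right": _per_bout_stride_lengths(pose_r, cfg),
        },
        bout_boundaries=bounds,
    )
    return rec, truth


def _per_bout_stride_durations(pose: FootPose, cfg: SimulationConfig) -> np.ndarray:
    n_sw = cfg.strides_per_bout + 1
    out = []
    for b in range(cfg.n_bouts):
        ics = pose.ic_times[b * n_sw : (b + 1) * n_sw]
        out.extend(np.diff(ics))
    return np.array(out)


def _per_bout_stride_lengths(pose: FootPose, cfg: SimulationConfig) -> np.ndarray:
    n_sw = cfg.strides_per_bout + 1
    out = []
    for b in range(cfg.n_bouts):
        p = pose.stance_positions[1 + b * n_sw : 1 + (b + 1) * n_sw]
        out.extend(np.linalg.norm(np.diff(p[:, :2], axis=0), axis=1))
    return np.array(out)
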