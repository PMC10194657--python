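"""Data model, CSV/JSON readers and writers, resampling and quality flags.

A :class:`Recording` bundles the synchronized streams of one trial: per-foot
IMUs (accelerometer m/s², gyroscope rad/s, optional magnetometer), a
lower-back IMU, optional 16-channel pressure insoles, optional time-of-flight
distance sensors (range limit 0.2 m, native 50 Hz) and optional reflective
marker trajectories for the stereophotogrammetric reference. All streams live
on a single common time vector (nominal 100 Hz) after synchronization.

On disk a recording is a JSON manifest naming one CSV per stream (first
column ``time_s``, remaining columns per the stream schema) plus per-stream
sample rates, units and inter-stream offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

G = 9.81  # gravity, m/s²
DPS_TO_RADS = np.pi / 180.0
DS_RANGE_M = 0.2  # distance-sensor saturation limit
DS_NATIVE_HZ = 50.0
MARKER_GAP_LIMIT_S = 0.5

PI_REGIONS = ("heel", "midfoot", "forefoot", "toe")

# 16-channel insole layout: normalized long-axis position (0 = heel, 1 = toe)
# and mediolateral position in [-0.5, 0.5], with the anatomical region of
# each sensing element. Four elements per region.
DEFAULT_PI_LAYOUT = tuple(
    (x, y, r)
    for r, xs in (
        ("heel", (0.05, 0.05, 0.15, 0.15)),
        ("midfoot", (0.35, 0.35, 0.45, 0.45)),
        ("forefoot", (0.65, 0.65, 0.75, 0.75)),
        ("toe", (0.88, 0.88, 0.96, 0.96)),
    )
    for x, y in zip(xs, (-0.15, 0.15, -0.15, 0.15))
)


@dataclass
class IMUSignal:
    """Tri-axial inertial streams in SI units (acc includes gravity)."""

    acc: np.ndarray  # (n, 3) m/s²
    gyr: np.ndarray  # (n, 3) rad/s
    mag: Optional[np.ndarray] = None  # (n, 3) arbitrary units

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.shape != self.gyr.shape or self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc and gyr must both be (n, 3)")
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)


@dataclass
class PressureInsoleSignal:
    """16 force-sensing-resistor channels with their insole layout."""

    channels: np.ndarray  # (n, 16), arbitrary force units, >= 0
    layout: np.ndarray  # (16, 2) normalized insole coordinates
    region: tuple[str, ...]  # per-channel anatomical cluster label

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.layout = np.asarray(self.layout, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != 16:
            raise ValueError("pressure insole must have exactly 16 channels")
        if self.layout.shape != (16, 2):
            raise ValueError("layout must be (16, 2)")
        if len(self.region) != 16:
            raise ValueError("region must label all 16 channels")
        bad = set(self.region) - set(PI_REGIONS)
        if bad:
            raise ValueError(f"unknown insole regions: {bad}")

    @classmethod
    def default_layout(cls, channels: np.ndarray) -> "PressureInsoleSignal":
        xy = np.array([(x, y) for x, y, _ in DEFAULT_PI_LAYOUT])
        regions = tuple(r for _, _, r in DEFAULT_PI_LAYOUT)
        return cls(channels=channels, layout=xy, region=regions)


@dataclass
class DistanceSignal:
    """Time-of-flight inter-leg range readings, clamped to the 0.2 m limit."""

    d: np.ndarray  # (n,) metres
    valid: np.ndarray  # (n,) True where reading < range limit
    native_rate_hz: float = DS_NATIVE_HZ

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


MARKER_NAMES = ("heel_left", "toe_left", "heel_right", "toe_right")
PELVIS_NAMES = ("pelvis_1", "pelvis_2", "pelvis_3", "pelvis_4")


@dataclass
class MarkerSet:
    """Heel/toe markers per foot plus a rigid 4-marker pelvis cluster.

    ``gap_mask[name]`` is True exactly where that marker is missing
    (coordinates are NaN there and finite elsewhere).
    """

    heel_left: np.ndarray
    toe_left: np.ndarray
    heel_right: np.ndarray
    toe_right: np.ndarray
    pelvis_cluster: np.ndarray  # (4, n, 3)
    gap_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def marker(self, name: str) -> np.ndarray:
        if name in MARKER_NAMES:
            return getattr(self, name)
        if name in PELVIS_NAMES:
            return self.pelvis_cluster[PELVIS_NAMES.index(name)]
        raise KeyError(name)

    def all_names(self) -> tuple[str, ...]:
        return MARKER_NAMES + PELVIS_NAMES


@dataclass
class QualityFlags:
    """Recording-level quality verdicts; ``discard`` folds the sensor-side ones."""

    data_loss: bool = False
    sync_failure: bool = False
    pi_degraded: bool = False
    marker_gap_over_half_second: bool = False

    @property
    def discard(self) -> bool:
        return self.data_loss or self.sync_failure or self.pi_degraded


@dataclass
class Recording:
    """One synchronized trial: all sensor streams on a common time vector."""

    recording_id: str
    fs: float
    t: np.ndarray
    imu_left: IMUSignal
    imu_right: IMUSignal
    imu_lowerback: Optional[IMUSignal] = None
    pi_left: Optional[PressureInsoleSignal] = None
    pi_right: Optional[PressureInsoleSignal] = None
    ds_left: Optional[DistanceSignal] = None
    ds_right: Optional[DistanceSignal] = None
    markers: Optional[MarkerSet] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("time vector must be 1-D with >= 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time vector must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


# ---------------------------------------------------------------------------
# manifest + CSV round trip
# ---------------------------------------------------------------------------

_IMU_COLS = ["acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]
_MAG_COLS = ["mag_x", "mag_y", "mag_z"]


def _imu_to_frame(t: np.ndarray, imu: IMUSignal) -> pd.DataFrame:
    data = {"time_s": t}
    data.update({c: imu.acc[:, i] for i, c in enumerate(_IMU_COLS[:3])})
    data.update({c: imu.gyr[:, i] for i, c in enumerate(_IMU_COLS[3:])})
    if imu.mag is not None:
        data.update({c: imu.mag[:, i] for i, c in enumerate(_MAG_COLS)})
    return pd.DataFrame(data)


def _frame_to_imu(df: pd.DataFrame, units: dict) -> IMUSignal:
    acc = df[_IMU_COLS[:3]].to_numpy(float)
    gyr = df[_IMU_COLS[3:]].to_numpy(float)
    if units.get("acc") == "g":
        acc = acc * G
    if units.get("gyr") == "dps":
        gyr = gyr * DPS_TO_RADS
    mag = df[_MAG_COLS].to_numpy(float) if set(_MAG_COLS) <= set(df.columns) else None
    return IMUSignal(acc=acc, gyr=gyr, mag=mag)


def write_recording(rec: Recording, out_dir: str | Path) -> Path:
    """Write a recording as a JSON manifest plus one CSV per stream.

    Returns the manifest path. Floats are written with 17 significant digits
    so a load/write round trip is lossless at double precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams: dict[str, dict] = {}

    def put(name: str, df: pd.DataFrame, rate: float, units: dict) -> None:
        fname = f"{name}.csv"
        df.to_csv(out / fname, index=False, float_format="%.17g")
        streams[name] = {"file": fname, "columns": list(df.columns), "rate_hz": rate, "units": units}

    si_imu = {"acc": "m/s^2", "gyr": "rad/s"}
    for name in ("imu_left", "imu_right", "imu_lowerback"):
        imu = getattr(rec, name)
        if imu is not None:
            put(name, _imu_to_frame(rec.t, imu), rec.fs, si_imu)
    for name in ("pi_left", "pi_right"):
        pi: Optional[PressureInsoleSignal] = getattr(rec, name)
        if pi is not None:
            df = pd.DataFrame({"time_s": rec.t})
            for i in range(16):
                df[f"ch{i:02d}"] = pi.channels[:, i]
            put(name, df, rec.fs, {"force": "au"})
            streams[name]["layout"] = pi.layout.tolist()
            streams[name]["region"] = list(pi.region)
    for name in ("ds_left", "ds_right"):
        ds: Optional[DistanceSignal] = getattr(rec, name)
        if ds is not None:
            df = pd.DataFrame({"time_s": rec.t, "d_m": ds.d, "valid": ds.valid.astype(int)})
            put(name, df, rec.fs, {"d": "m"})
            streams[name]["native_rate_hz"] = ds.native_rate_hz
    if rec.markers is not None:
        df = pd.DataFrame({"time_s": rec.t})
        for mname in rec.markers.all_names():
            traj = rec.markers.marker(mname)
            for ax, col in zip(range(3), "xyz"):
                df[f"{mname}_{col}"] = traj[:, ax]
        put("markers", df, rec.fs, {"pos": "m"})

    manifest = {
        "recording_id": rec.recording_id,
        "fs": rec.fs,
        "streams": streams,
        "offsets_s": {name: 0.0 for name in streams},
        "meta": rec.meta,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def load_recording(manifest_path: str | Path) -> Recording:
    """Load a recording from its JSON manifest.

    Units are converted to SI at ingest (dps → rad/s, g → m/s²). Both foot
    IMUs are mandatory; insoles, distance sensors and markers are optional.
    """
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    base = mpath.parent
    streams = manifest["streams"]
    for required in ("imu_left", "imu_right"):
        if required not in streams:
            raise ValueError(f"mandatory stream '{required}' missing from manifest")

    def read(name: str) -> Optional[pd.DataFrame]:
        if name not in streams:
            return None
        df = pd.read_csv(base / streams[name]["file"])
        off = manifest.get("offsets_s", {}).get(name, 0.0)
        if off:
            df["time_s"] = df["time_s"] + off
        return df

    t = None
    imus: dict[str, Optional[IMUSignal]] = {}
    for name in ("imu_left", "imu_right", "imu_lowerback"):
        df = read(name)
        if df is None:
            imus[name] = None
            continue
        imus[name] = _frame_to_imu(df, streams[name].get("units", {}))
        if t is None:
            t = df["time_s"].to_numpy(float)

    pis: dict[str, Optional[PressureInsoleSignal]] = {}
    for name in ("pi_left", "pi_right"):
        df = read(name)
        if df is None:
            pis[name] = None
            continue
        ch = df[[f"ch{i:02d}" for i in range(16)]].to_numpy(float)
        info = streams[name]
        if "layout" in info:
            pis[name] = PressureInsoleSignal(
                channels=ch, layout=np.array(info["layout"]), region=tuple(info["region"])
            )
        else:
            pis[name] = PressureInsoleSignal.default_layout(ch)

    dss: dict[str, Optional[DistanceSignal]] = {}
    for name in ("ds_left", "ds_right"):
        df = read(name)
        if df is None:
            dss[name] = None
            continue
        dss[name] = DistanceSignal(
            d=df["d_m"].to_numpy(float),
            valid=df["valid"].to_numpy(bool),
            native_rate_hz=streams[name].get("native_rate_hz", DS_NATIVE_HZ),
        )

    markers = None
    dfm = read("markers")
    if dfm is not None:
        def traj(name: str) -> np.ndarray:
            return dfm[[f"{name}_{c}" for c in "xyz"]].to_numpy(float)

        trajs = {n: traj(n) for n in MARKER_NAMES}
        pelvis = np.stack([traj(n) for n in PELVIS_NAMES])
        gap_mask = {
            n: np.isnan(trajs[n]).any(axis=1) if n in trajs else np.isnan(traj(n)).any(axis=1)
            for n in MARKER_NAMES + PELVIS_NAMES
        }
        markers = MarkerSet(
            heel_left=trajs["heel_left"],
            toe_left=trajs["toe_left"],
            heel_right=trajs["heel_right"],
            toe_right=trajs["toe_right"],
            pelvis_cluster=pelvis,
            gap_mask=gap_mask,
        )

    if t is None:
        raise ValueError("no IMU stream found to define the time base")

    return Recording(
        recording_id=manifest.get("recording_id", mpath.parent.name),
        fs=float(manifest["fs"]),
        t=t,
        imu_left=imus["imu_left"],
        imu_right=imus["imu_right"],
        imu_lowerback=imus["imu_lowerback"],
        pi_left=pis["pi_left"],
        pi_right=pis["pi_right"],
        ds_left=dss["ds_left"],
        ds_right=dss["ds_right"],
        markers=markers,
        meta=manifest.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# resampling / synchronization
# ---------------------------------------------------------------------------


def _interp_columns(t_new: np.ndarray, t_old: np.ndarray, y: np.ndarray) -> np.ndarray:
    y = np.atleast_2d(y.T).T
    out = np.empty((len(t_new), y.shape[1]))
    for j in range(y.shape[1]):
        out[:, j] = np.interp(t_new, t_old, y[:, j])
    return out


def resample_and_sync(rec: Recording, fs_target: float) -> Recording:
    """Interpolate every stream onto one common grid at ``fs_target``.

    Linear interpolation for continuous channels; the distance-sensor
    validity flag is carried by nearest neighbour. Streams recorded at a
    lower native rate (the 50 Hz distance sensor) are upsampled the same
    way. The grid spans the recording's own time range, so identical input
    and output rates reproduce the input samplewise.
    """
    t_old = rec.t
    if np.any(np.diff(t_old) <= 0):
        raise ValueError("non-monotone time vector")
    n_new = int(np.floor((t_old[-1] - t_old[0]) * fs_target)) + 1
    t_new = t_old[0] + np.arange(n_new) / fs_target
    if len(t_new) < 2:
        raise ValueError("time ranges do not overlap enough to resample")

    def imu_rs(imu: Optional[IMUSignal]) -> Optional[IMUSignal]:
        if imu is None:
            return None
        return IMUSignal(
            acc=_interp_columns(t_new, t_old, imu.acc),
            gyr=_interp_columns(t_new, t_old, imu.gyr),
            mag=None if imu.mag is None else _interp_columns(t_new, t_old, imu.mag),
        )

    def pi_rs(pi: Optional[PressureInsoleSignal]) -> Optional[PressureInsoleSignal]:
        if pi is None:
            return None
        return replace(pi, channels=_interp_columns(t_new, t_old, pi.channels))

    def ds_rs(ds: Optional[DistanceSignal]) -> Optional[DistanceSignal]:
        if ds is None:
            return None
        d = np.interp(t_new, t_old, ds.d)
        idx = np.clip(np.searchsorted(t_old, t_new), 0, len(t_old) - 1)
        left = np.clip(idx - 1, 0, len(t_old) - 1)
        nearer = np.where(np.abs(t_old[idx] - t_new) <= np.abs(t_new - t_old[left]), idx, left)
        return DistanceSignal(d=d, valid=ds.valid[nearer], native_rate_hz=ds.native_rate_hz)

    markers = rec.markers
    if markers is not None:
        def m_rs(y: np.ndarray) -> np.ndarray:
            return _interp_columns(t_new, t_old, y)

        gap_mask = {}
        for name in markers.all_names():
            mask = markers.gap_mask.get(name, np.zeros(len(t_old), bool))
            idx = np.clip(np.searchsorted(t_old, t_new), 0, len(t_old) - 1)
            gap_mask[name] = mask[idx]
        markers = MarkerSet(
            heel_left=m_rs(markers.heel_left),
            toe_left=m_rs(markers.toe_left),
            heel_right=m_rs(markers.heel_right),
            toe_right=m_rs(markers.toe_right),
            pelvis_cluster=np.stack([m_rs(markers.pelvis_cluster[i]) for i in range(4)]),
            gap_mask=gap_mask,
        )

    return Recording(
        recording_id=rec.recording_id,
        fs=fs_target,
        t=t_new,
        imu_left=imu_rs(rec.imu_left),
        imu_right=imu_rs(rec.imu_right),
        imu_lowerback=imu_rs(rec.imu_lowerback),
        pi_left=pi_rs(rec.pi_left),
        pi_right=pi_rs(rec.pi_right),
        ds_left=ds_rs(rec.ds_left),
        ds_right=ds_rs(rec.ds_right),
        markers=markers,
        meta=dict(rec.meta),
    )


# ---------------------------------------------------------------------------
# quality flags
# ---------------------------------------------------------------------------


def _pi_degraded(pi: PressureInsoleSignal) -> bool:
    # stuck (constant over the whole trial) or negative-saturated >10% of samples
    for j in range(16):
        col = pi.channels[:, j]
        if np.ptp(col) == 0.0:
            return True
        if np.mean(col < 0) > 0.10:
            return True
    return False


def _longest_gap_s(mask: np.ndarray, t: np.ndarray) -> float:
    if not mask.any():
        return 0.0
    longest = 0.0
    run_start = None
    for i, m in enumerate(mask):
        if m and run_start is None:
            run_start = i
        elif not m and run_start is not None:
            longest = max(longest, t[i - 1] - t[run_start] + (t[1] - t[0]))
            run_start = None
    if run_start is not None:
        longest = max(longest, t[-1] - t[run_start] + (t[1] - t[0]))
    return longest


def flag_quality(rec: Recording) -> QualityFlags:
    """Compute recording-level quality flags (a pure function of the data).

    ``pi_degraded`` fires on stuck or negative-saturated insole channels;
    the marker flag fires when any foot-marker gap exceeds 0.5 s. Data-loss
    and sync flags fire on NaNs in inertial streams or a broken time base.
    """
    flags = QualityFlags()
    for imu in (rec.imu_left, rec.imu_right, rec.imu_lowerback):
        if imu is not None and (np.isnan(imu.acc).any() or np.isnan(imu.gyr).any()):
            flags.data_loss = True
    dt = np.diff(rec.t)
    if np.any(np.abs(dt - 1.0 / rec.fs) > 1e-6):
        flags.sync_failure = True
    for pi in (rec.pi_left, rec.pi_right):
        if pi is not None and _pi_degraded(pi):
            flags.pi_degraded = True
    if rec.markers is not None:
        for name in MARKER_NAMES:  # reference-side rule: foot markers only
            mask = rec.markers.gap_mask.get(name)
            if mask is not None and _longest_gap_s(np.asarray(mask, bool), rec.t) > MARKER_GAP_LIMIT_S:
                flags.marker_gap_over_half_second = True
    return flags
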