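"""Sensor noise characterization and pre-session static spot checks.

Random-error characterization follows IEEE-style sensor performance
definitions: per-axis standard deviation over a 100 s static acquisition
for both accelerometer and gyroscope, and gyroscope bias instability as
the minimum of the overlapping Allan deviation computed from a long (hours)
static recording. Units mirror field reporting conventions: mg for
accelerometer STD, dps for gyroscope STD and bias instability.

Fleet reference ceilings (the maxima observed across the deployed units)
are 3.31 mg and 0.13 dps; a sensor whose static STD exceeds a ceiling by
more than 15% fails and should be recalibrated or discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import G, IMUSignal

ACC_REF_MAX_MG = 3.31
GYR_REF_MAX_DPS = 0.13
REJECT_MARGIN = 1.15  # fail when exceeding a ceiling by >15%
MG_TO_MS2 = 1e-3 * G
DPS_TO_RADS = math.pi / 180.0

SPOT_CHECK_DURATION_S = 60.0
STATIC_STD_DURATION_S = 100.0
MOTION_STD_LIMIT = 2.1  # m/s²; above this the segment is not static
ACC_NORM_TOL = 0.3  # m/s² allowed deviation of mean ‖acc‖ from g


@dataclass
class NoiseCharacterization:
    acc_std: np.ndarray  # per-axis, m/s²
    gyr_std: np.ndarray  # per-axis, rad/s
    gyr_bias_instability_dps: float | None
    passed: bool

    @property
    def acc_std_mg(self) -> np.ndarray:
        return self.acc_std / MG_TO_MS2

    @property
    def gyr_std_dps(self) -> np.ndarray:
        return self.gyr_std / DPS_TO_RADS


@dataclass
class SpotCheck:
    gyr_bias: np.ndarray  # per-axis mean over the static minute, rad/s
    ok: bool


# ---------------------------------------------------------------------------


def static_std(signal: np.ndarray, fs: float, duration_s: float = STATIC_STD_DURATION_S) -> np.ndarray:
    """Per-axis sample STD over the first ``duration_s`` seconds of a static
    segment (the standard 100 s characterization window)."""
    sig = np.atleast_2d(np.asarray(signal, dtype=float).T).T
    n = int(round(duration_s * fs))
    if len(sig) < n:
        raise ValueError(f"static segment shorter than {duration_s} s")
    return np.std(sig[:n], axis=0, ddof=1)


def allan_deviation(y: np.ndarray, fs: float, taus: np.ndarray) -> np.ndarray:
    """Overlapping Allan deviation of a rate signal at averaging times taus."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    theta = np.concatenate([[0.0], np.cumsum(y) / fs])  # integrated angle
    out = np.empty(len(taus))
    for i, tau in enumerate(taus):
        m = int(round(tau * fs))
        if m < 1 or 2 * m >= n:
            out[i] = np.nan
            continue
        d = theta[2 * m :] - 2.0 * theta[m : n + 1 - m] + theta[: n + 1 - 2 * m]
        out[i] = math.sqrt(float(np.mean(d**2)) / (2.0 * (m / fs) ** 2))
    return out


def default_taus(n_samples: int, fs: float, n_points: int = 30) -> np.ndarray:
    """Log-spaced averaging times from 2 samples to a tenth of the record."""
    t_min = 2.0 / fs
    t_max = n_samples / fs / 10.0
    if t_max <= t_min:
        raise ValueError("recording too short for an Allan analysis")
    return np.logspace(math.log10(t_min), math.log10(t_max), n_points)


def allan_bias_instability(
    gyr: np.ndarray, fs: float, taus: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Gyroscope bias instability from a long static acquisition.

    Per axis, the bias instability is the minimum of the overlapping Allan
    deviation over the tau grid; the worst axis is reported (in dps, the
    raw deviation minimum without a correction factor). Returns
    (bias_instability_dps, taus, sigma (n_taus × n_axes) in input units).
    """
    g = np.atleast_2d(np.asarray(gyr, dtype=float).T).T
    n = len(g)
    if taus is None:
        taus = default_taus(n, fs)
    if n / fs + 1e-9 < 10.0 * float(np.max(taus)):
        raise ValueError("recording shorter than 10× the largest averaging time")
    sigma = np.stack([allan_deviation(g[:, ax], fs, taus) for ax in range(g.shape[1])], axis=1)
    minima = np.nanmin(sigma, axis=0)
    worst = float(np.max(minima))
    return worst / DPS_TO_RADS, taus, sigma


def characterize_noise(
    imu: IMUSignal,
    fs: float,
    duration_s: float = STATIC_STD_DURATION_S,
    gyr_long_static: np.ndarray | None = None,
    long_static_fs: float | None = None,
) -> NoiseCharacterization:
    """Static STD characterization with the fleet pass/fail rule; bias
    instability is included when a long static gyro record is supplied."""
    acc_sd = static_std(imu.acc, fs, duration_s)
    gyr_sd = static_std(imu.gyr, fs, duration_s)
    bi = None
    if gyr_long_static is not None:
        bi, _, _ = allan_bias_instability(gyr_long_static, long_static_fs or fs)
    passed = bool(
        np.all(acc_sd <= REJECT_MARGIN * ACC_REF_MAX_MG * MG_TO_MS2)
        and np.all(gyr_sd <= REJECT_MARGIN * GYR_REF_MAX_DPS * DPS_TO_RADS)
    )
    return NoiseCharacterization(
        acc_std=acc_sd, gyr_std=gyr_sd, gyr_bias_instability_dps=bi, passed=passed
    )


def spot_check(imu: IMUSignal, fs: float, duration_s: float = SPOT_CHECK_DURATION_S) -> SpotCheck:
    """Pre-session 60 s static check: gyroscope bias (per-axis mean, handed
    to the trajectory stage for removal) and sensor sanity.

    ``ok`` requires the mean accelerometer norm within 9.81 ± 0.3 m/s²
    (tilt-invariant) and static STDs under the fleet ceilings. Raises when
    the segment is not static (accelerometer STD above 2.1 m/s²).
    """
    n = int(round(duration_s * fs))
    if len(imu.acc) < n:
        raise ValueError(f"spot check requires {duration_s} s of static data")
    acc = imu.acc[:n]
    gyr = imu.gyr[:n]
    acc_norm = np.linalg.norm(acc, axis=1)
    if np.std(acc_norm) > MOTION_STD_LIMIT:
        raise ValueError("not static: motion detected during spot check")
    bias = gyr.mean(axis=0)
    std_ok = bool(
        np.all(np.std(acc, axis=0, ddof=1) <= REJECT_MARGIN * ACC_REF_MAX_MG * MG_TO_MS2)
        and np.all(np.std(gyr, axis=0, ddof=1) <= REJECT_MARGIN * GYR_REF_MAX_DPS * DPS_TO_RADS)
    )
    ok = bool(abs(float(acc_norm.mean()) - G) <= ACC_NORM_TOL and std_ok)
    return SpotCheck(gyr_bias=bias, ok=ok)
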