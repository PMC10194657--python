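"""Strides, walking bouts and digital mobility outcomes (DMOs).

A stride is the interval between two consecutive initial contacts of the
same foot, with its stance taken from the enclosed final contact. Strides
pass a plausibility filter (duration in [0.2, 3] s, length ≥ 0.15 m, bounds
inclusive); ipsilateral sequences split at breaks of 3 s or more; left and
right sequences overlapping in time merge into walking bouts, whose first
and last stride are trimmed as gait-initiation/termination transients; a
bout is eligible only if at least two strides per side remain.

Per-bout DMOs:
    cadence     = [Σ_j 60/duration_j / n] × 2          (steps/min)
    speed       = Σ_j length_j/duration_j / n          (m/s)
plus bout duration/length, stride count, mean stride length and mean stance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import DistanceSignal
from .events import FC, IC, GaitEvent, sort_events

MIN_STRIDE_DURATION_S = 0.2
MAX_STRIDE_DURATION_S = 3.0
MIN_STRIDE_LENGTH_M = 0.15
MAX_INTER_STRIDE_GAP_S = 3.0
MIN_STRIDES_PER_SIDE = 2


@dataclass
class Stride:
    """IC-to-IC interval of one foot with temporal and spatial attributes."""

    side: str
    t_ic: float
    t_fc: float  # enclosed FC (end of this stride's stance)
    t_ic_next: float
    length: float = math.nan  # m, attached by the trajectory stage
    velocity: float = math.nan  # m/s
    valid: bool = True
    ds_verified: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (self.t_ic < self.t_fc < self.t_ic_next):
            raise ValueError("stride requires t_ic < t_fc < t_ic_next")

    @property
    def duration(self) -> float:
        return self.t_ic_next - self.t_ic

    @property
    def stance(self) -> float:
        return self.t_fc - self.t_ic


@dataclass
class DMOSet:
    wb_duration: float  # s
    wb_length: float  # m
    n_strides: int
    cadence: float  # steps/min
    avg_stride_length: float  # m
    walking_speed: float  # m/s
    avg_stance: float  # s

    def as_dict(self) -> dict[str, float]:
        return {
            "wb_duration": self.wb_duration,
            "wb_length": self.wb_length,
            "n_strides": self.n_strides,
            "cadence": self.cadence,
            "avg_stride_length": self.avg_stride_length,
            "walking_speed": self.walking_speed,
            "avg_stance": self.avg_stance,
        }


@dataclass
class WalkingBout:
    """Ordered bilateral stride set (post-trimming) with its DMOs."""

    strides: list[Stride]
    t_start: float
    t_end: float
    dmo: Optional[DMOSet] = field(default=None)

    def n_per_side(self, side: str) -> int:
        return sum(1 for s in self.strides if s.side == side)


# ---------------------------------------------------------------------------


def build_strides(events: Sequence[GaitEvent]) -> list[Stride]:
    """One stride per consecutive ipsilateral IC pair; stance from the FC
    enclosed between them. Trailing unpaired ICs emit no stride."""
    out: list[Stride] = []
    for side in ("left", "right"):
        evs = sort_events([e for e in events if e.side == side])
        ics = [e for e in evs if e.kind == IC]
        fcs = [e for e in evs if e.kind == FC]
        for a, b in zip(ics, ics[1:]):
            enclosed = [f for f in fcs if a.t < f.t < b.t]
            if not enclosed:
                continue
            out.append(Stride(side=side, t_ic=a.t, t_fc=enclosed[0].t, t_ic_next=b.t))
    out.sort(key=lambda s: s.t_ic)
    return out


def select_strides(strides: Sequence[Stride]) -> list[Stride]:
    """Flag stride validity: duration within [0.2, 3] s (inclusive) and
    length ≥ 0.15 m. Strides with no measured length are invalid."""
    for s in strides:
        dur_ok = MIN_STRIDE_DURATION_S <= s.duration <= MAX_STRIDE_DURATION_S
        len_ok = (not math.isnan(s.length)) and s.length >= MIN_STRIDE_LENGTH_M
        s.valid = dur_ok and len_ok
    return list(strides)


def verify_with_distance_sensor(
    stride: Stride, ds: Optional[DistanceSignal], t: Optional[np.ndarray]
) -> Optional[bool]:
    """True iff at least one in-range inter-leg reading (a contralateral
    swing pass) falls within the stride; None when no sensor is present.
    Verification annotates the stride, it never rejects it."""
    if ds is None or t is None:
        stride.ds_verified = None
        return None
    sel = (t >= stride.t_ic) & (t <= stride.t_ic_next)
    stride.ds_verified = bool(np.any(ds.valid[sel]))
    return stride.ds_verified


# ---------------------------------------------------------------------------


def _sequences(strides: list[Stride], max_gap_s: float) -> list[list[Stride]]:
    """Split one side's strides where the IC-next→IC gap reaches 3 s."""
    seqs: list[list[Stride]] = []
    for s in sorted(strides, key=lambda x: x.t_ic):
        if seqs and s.t_ic - seqs[-1][-1].t_ic_next < max_gap_s:
            seqs[-1].append(s)
        else:
            seqs.append([s])
    return seqs


def build_walking_bouts(
    left: Sequence[Stride],
    right: Sequence[Stride],
    max_gap_s: float = MAX_INTER_STRIDE_GAP_S,
    min_per_side: int = MIN_STRIDES_PER_SIDE,
    trim: bool = True,
) -> list[WalkingBout]:
    """Assemble bouts from valid strides of both sides.

    Per side, consecutive strides separated by less than 3 s form a
    sequence; left and right sequences whose time spans overlap merge into
    one bout (transitively). The chronologically first and last stride of
    each merged bout are removed as initiation/termination transients, and
    the bout is kept only if ≥2 strides per side remain.
    """
    seqs: list[tuple[str, list[Stride]]] = []
    for side, strides in (("left", list(left)), ("right", list(right))):
        strides = [s for s in strides if s.valid]
        seqs.extend((side, seq) for seq in _sequences(strides, max_gap_s))
    if not seqs:
        return []

    spans = [(seq[0].t_ic, seq[-1].t_ic_next, i) for i, (_, seq) in enumerate(seqs)]
    spans.sort()
    groups: list[list[int]] = []
    cur_end = -math.inf
    for a, b, i in spans:
        if groups and a < cur_end:  # positive overlap with the running group
            groups[-1].append(i)
            cur_end = max(cur_end, b)
        else:
            groups.append([i])
            cur_end = b

    bouts: list[WalkingBout] = []
    for group in groups:
        strides = sorted(
            (s for i in group for s in seqs[i][1]), key=lambda s: (s.t_ic, s.side)
        )
        if trim and len(strides) >= 2:
            strides = strides[1:-1]
        if not strides:
            continue
        wb = WalkingBout(
            strides=strides,
            t_start=min(s.t_ic for s in strides),
            t_end=max(s.t_ic_next for s in strides),
        )
        if wb.n_per_side("left") >= min_per_side and wb.n_per_side("right") >= min_per_side:
            wb.dmo = compute_dmos(wb)
            bouts.append(wb)
    return bouts


def compute_dmos(wb: WalkingBout) -> DMOSet:
    """Per-bout digital mobility outcomes from the retained strides."""
    if not wb.strides:
        raise ValueError("cannot compute DMOs of an empty bout")
    durations = np.array([s.duration for s in wb.strides])
    lengths = np.array([s.length for s in wb.strides])
    stances = np.array([s.stance for s in wb.strides])
    n = len(wb.strides)
    cadence = float(np.sum(60.0 / durations) / n * 2.0)
    speed = float(np.sum(lengths / durations) / n)
    sum_left = float(sum(s.length for s in wb.strides if s.side == "left"))
    sum_right = float(sum(s.length for s in wb.strides if s.side == "right"))
    return DMOSet(
        wb_duration=wb.t_end - wb.t_start,
        wb_length=0.5 * (sum_left + sum_right),
        n_strides=n,
        cadence=cadence,
        avg_stride_length=float(np.mean(lengths)),
        walking_speed=speed,
        avg_stance=float(np.mean(stances)),
    )
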