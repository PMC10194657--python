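"""Gait event and interval primitives shared across detection modules."""

from __future__ import annotations

from dataclasses import dataclass

IC = "IC"  # initial contact: foot strikes the ground
FC = "FC"  # final contact: foot leaves the ground (toe-off)

SOURCE_PI = "PI"
SOURCE_IMU = "IMU"
SOURCE_FUSED = "FUSED"
SOURCE_MARKER = "MARKER"
SOURCE_TRUTH = "TRUTH"


@dataclass(frozen=True)
class GaitEvent:
    """A timestamped initial or final contact of one foot."""

    t: float
    kind: str  # IC | FC
    side: str  # left | right
    source: str  # PI | IMU | FUSED | MARKER | TRUTH

    def __post_init__(self) -> None:
        if self.kind not in (IC, FC):
            raise ValueError(f"kind must be IC or FC, got {self.kind!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left or right, got {self.side!r}")


def sort_events(events: list[GaitEvent]) -> list[GaitEvent]:
    return sorted(events, key=lambda e: (e.t, e.kind))


def enforce_alternation(events: list[GaitEvent]) -> list[GaitEvent]:
    """Drop the later of two consecutive same-kind events (per call, one side)."""
    out: list[GaitEvent] = []
    for ev in sort_events(events):
        if out and out[-1].kind == ev.kind:
            continue
        out.append(ev)
    return out


def check_alternation(events: list[GaitEvent]) -> bool:
    evs = sort_events(events)
    return all(a.kind != b.kind for a, b in zip(evs, evs[1:]))
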