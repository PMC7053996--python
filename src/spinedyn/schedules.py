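"""Imaging-session schedules.

Two layouts are supported:

``baseline10``
    Ten consecutive daily sessions (D1..D10) under normal visual
    experience; the layout used for all baseline-dynamics analyses.

``deprivation``
    Three daily baseline sessions (BL1..BL3) followed by imaging on
    days 1, 2, 3 and 7 after binocular enucleation or sham surgery
    (VD1, VD2, VD3, VD7).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Schedule", "get_schedule", "SCHEDULES"]


@dataclass(frozen=True)
class Schedule:
    """Ordered session layout with baseline/post phase tags."""

    name: str
    sessions: tuple[str, ...]
    days: tuple[int, ...]          # day offsets, consecutive days differ by 1
    baseline: tuple[str, ...]      # sessions forming the baseline window

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def post(self) -> tuple[str, ...]:
        return tuple(s for s in self.sessions if s not in self.baseline)

    def index(self, session: str) -> int:
        return self.sessions.index(session)

    def is_consecutive(self, a: str, b: str) -> bool:
        """True if *b* is the calendar day after *a* (daily transition)."""
        ia, ib = self.index(a), self.index(b)
        return ib == ia + 1 and self.days[ib] - self.days[ia] == 1


SCHEDULES: dict[str, Schedule] = {
    "baseline10": Schedule(
        name="baseline10",
        sessions=tuple(f"D{i}" for i in range(1, 11)),
        days=tuple(range(1, 11)),
        baseline=tuple(f"D{i}" for i in range(1, 11)),
    ),
    "deprivation": Schedule(
        name="deprivation",
        sessions=("BL1", "BL2", "BL3", "VD1", "VD2", "VD3", "VD7"),
        days=(1, 2, 3, 4, 5, 6, 10),
        baseline=("BL1", "BL2", "BL3"),
    ),
}


def get_schedule(name: str) -> Schedule:
    try:
        return SCHEDULES[name]
    except KeyError:
        raise KeyError(
            f"unknown schedule {name!r}; valid schedules: {sorted(SCHEDULES)}"
        ) from None
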