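"""Step segmentation from heel-strike event streams.

A *right step* spans left heel strike -> right heel strike and a *left step*
spans right heel strike -> left heel strike, so a segment takes the side of
the foot that lands at its end.  Windows are half-open ``[start, end)`` so a
sample at a heel strike belongs to exactly one step.  Data before the first
and after the last heel strike belong to no step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = ["StepSegment", "segment_steps"]


@dataclass(frozen=True)
class StepSegment:
    start_s: float
    end_s: float
    side: str  # "L" or "R"

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("step segment must have end_s > start_s")
        if self.side not in ("L", "R"):
            raise ValueError(f"step side must be 'L' or 'R', got {self.side!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def segment_steps(heel_strikes) -> list[StepSegment]:
    """Convert an ordered ``(time_s, side)`` event stream into step segments.

    Each consecutive pair of alternating-side events yields one segment whose
    side is the landing foot's side.  Consecutive same-side events (possible
    with an imperfect upstream detector) are skipped with a logged warning
    rather than raising.
    """
    events = list(heel_strikes)
    if len(events) < 2:
        raise ValueError("insufficient events: need at least 2 heel strikes")
    times = [t for t, _ in events]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("heel-strike times must be strictly increasing")
    for _, side in events:
        if side not in ("L", "R"):
            raise ValueError(f"heel-strike side must be 'L' or 'R', got {side!r}")

    segments = []
    n_dropped = 0
    for (t1, s1), (t2, s2) in zip(events, events[1:]):
        if s1 == s2:
            n_dropped += 1
            continue
        segments.append(StepSegment(t1, t2, s2))
    if n_dropped:
        logger.warning(
            "dropped %d same-side consecutive heel-strike pair(s) during segmentation",
            n_dropped,
        )
    return segments
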