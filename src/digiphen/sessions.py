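"""Active phone use sessions from phone status event streams.

An active phone use session is the span between the device being unlocked and
its next return to standby (or shutdown): the period during which the
participant is assumed to be actively using the smartphone. Sessions are
half-open intervals [start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .events import PhoneState, PhoneStatusEvent

log = logging.getLogger(__name__)

_TERMINATORS = (PhoneState.STANDBY, PhoneState.SHUTDOWN)


@dataclass(frozen=True, slots=True)
class ActiveSession:
    participant_id: str
    start: float
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"session requires start < end, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start


def derive_sessions(events: Sequence[PhoneStatusEvent]) -> list[ActiveSession]:
    """Derive active phone use sessions for a single participant.

    State machine over the sorted status stream: a session opens at an
    UNLOCKED event and closes at the next STANDBY or SHUTDOWN. Conventions for
    the cases the event grammar leaves open:

    - SHUTDOWN terminates an open session (powering off ends active use);
      BOOTED never opens one.
    - Repeated UNLOCKED events without an intervening terminator extend the
      same session rather than starting a new one.
    - A trailing UNLOCKED with no terminator before the end of the stream is
      dropped (its true duration is unknown) and counted in the log.
    - Zero-length spans (terminator at the unlock timestamp) are discarded.
    """
    if not events:
        return []
    pids = {e.participant_id for e in events}
    if len(pids) > 1:
        raise ValueError(f"derive_sessions expects one participant, got {sorted(pids)}")
    last_t = -float("inf")
    for e in events:
        if e.timestamp < last_t:
            raise ValueError(f"phone status events not sorted at t={e.timestamp}")
        last_t = e.timestamp

    sessions: list[ActiveSession] = []
    open_start: float | None = None
    dropped_open = 0
    zero_length = 0
    for e in events:
        if e.state is PhoneState.UNLOCKED:
            if open_start is None:
                open_start = e.timestamp
        elif e.state in _TERMINATORS and open_start is not None:
            if e.timestamp > open_start:
                sessions.append(ActiveSession(e.participant_id, open_start, e.timestamp))
            else:
                zero_length += 1
            open_start = None
    if open_start is not None:
        dropped_open += 1
    if dropped_open or zero_length:
        log.debug(
            "participant %s: dropped %d unterminated open(s), %d zero-length span(s)",
            events[0].participant_id, dropped_open, zero_length,
        )
    return sessions


def write_sessions(sessions: Sequence[ActiveSession], path: str | Path) -> Path:
    import csv

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "start", "end", "duration"])
        for s in sessions:
            writer.writerow([s.participant_id, repr(s.start), repr(s.end), repr(s.duration)])
    return path
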