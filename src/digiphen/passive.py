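"""Passive smartphone and wearable features tied to active phone use sessions.

Features derived here:

7.  SD in ambient light (lux) while actively using the phone — one sample SD
    of the light-sensor readings falling inside each session;
8.  wearable step count during each session;
9.  active session duration (seconds);
10. number of new apps added per day — operationalised as the count of package
    names appearing in the participant's app-event stream for the first time
    on each local day, after a burn-in period that absorbs pre-installed apps.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .events import AppEvent, LightReading, StepRecord
from .features import Feature, FeatureObservation
from .notifications import local_day_index
from .sessions import ActiveSession

DEFAULT_MIN_LIGHT_READINGS = 2
DEFAULT_BURN_IN_DAYS = 1


def _session_arrays(sessions: Sequence[ActiveSession]):
    starts = np.array([s.start for s in sessions], dtype=float)
    ends = np.array([s.end for s in sessions], dtype=float)
    if np.any(np.diff(starts) < 0):
        raise ValueError("sessions not sorted by start")
    return starts, ends


def _assign_to_sessions(times: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Index of the session containing each time (half-open [start, end)), or −1."""
    idx = np.searchsorted(starts, times, side="right") - 1
    ok = (idx >= 0) & (times < ends[np.clip(idx, 0, None)])
    return np.where(ok, idx, -1)


def ambient_light_sd(
    light: Sequence[LightReading],
    sessions: Sequence[ActiveSession],
    enrollment_epoch: float,
    utc_offset_hours: float = 0.0,
    min_readings: int = DEFAULT_MIN_LIGHT_READINGS,
) -> list[FeatureObservation]:
    """Sample SD (n−1) of illuminance within each session with enough readings."""
    if min_readings < 2:
        raise ValueError("min_readings must be >= 2 for a sample SD")
    if not sessions:
        return []
    starts, ends = _session_arrays(sessions)
    times = np.array([r.timestamp for r in light], dtype=float)
    lux = np.array([r.illuminance for r in light], dtype=float)
    idx = _assign_to_sessions(times, starts, ends)
    obs = []
    for i, s in enumerate(sessions):
        values = lux[idx == i]
        if len(values) < min_readings:
            continue
        day = float(local_day_index(s.start, enrollment_epoch, utc_offset_hours))
        obs.append(
            FeatureObservation(Feature.AMBIENT_LIGHT_SD, s.participant_id, float(np.std(values, ddof=1)), day)
        )
    return obs


def steps_in_sessions(
    steps: Sequence[StepRecord],
    sessions: Sequence[ActiveSession],
    enrollment_epoch: float,
    utc_offset_hours: float = 0.0,
) -> list[FeatureObservation]:
    """Total wearable steps recorded inside each session (0 when none)."""
    if not sessions:
        return []
    starts, ends = _session_arrays(sessions)
    times = np.array([r.timestamp for r in steps], dtype=float)
    counts = np.array([r.steps for r in steps], dtype=float)
    idx = _assign_to_sessions(times, starts, ends)
    totals = np.zeros(len(sessions))
    inside = idx >= 0
    np.add.at(totals, idx[inside], counts[inside])
    return [
        FeatureObservation(
            Feature.STEPS_IN_SESSION,
            s.participant_id,
            float(totals[i]),
            float(local_day_index(s.start, enrollment_epoch, utc_offset_hours)),
        )
        for i, s in enumerate(sessions)
    ]


def session_durations(
    sessions: Sequence[ActiveSession],
    enrollment_epoch: float,
    utc_offset_hours: float = 0.0,
) -> list[FeatureObservation]:
    """Duration of each active phone use session, in seconds."""
    return [
        FeatureObservation(
            Feature.SESSION_DURATION,
            s.participant_id,
            s.duration,
            float(local_day_index(s.start, enrollment_epoch, utc_offset_hours)),
        )
        for s in sessions
    ]


def daily_new_apps(
    app_events: Sequence[AppEvent],
    enrollment_epoch: float,
    utc_offset_hours: float = 0.0,
    burn_in_days: int = DEFAULT_BURN_IN_DAYS,
) -> list[FeatureObservation]:
    """Count of packages first seen on each local day after the burn-in.

    The stream has no explicit install events, so "new app added" is read as
    the first appearance of a package name. Days 0..burn_in_days−1 absorb the
    pre-installed packages and emit no observation. Every later day up to the
    last day with any app event emits a count, including 0.
    """
    if not app_events:
        return []
    pids = {e.participant_id for e in app_events}
    if len(pids) != 1:
        raise ValueError(f"daily_new_apps expects one participant, got {sorted(pids)}")
    pid = pids.pop()
    days = local_day_index([e.timestamp for e in app_events], enrollment_epoch, utc_offset_hours)
    first_day: dict[str, float] = {}
    for e, d in zip(app_events, days):
        if e.package not in first_day or d < first_day[e.package]:
            first_day[e.package] = d
    last_day = int(np.max(days))
    counts = {d: 0 for d in range(burn_in_days, last_day + 1)}
    for d in first_day.values():
        if d >= burn_in_days:
            counts[int(d)] += 1
    return [
        FeatureObservation(Feature.NEW_APPS_DAILY, pid, float(n), float(d))
        for d, n in sorted(counts.items())
    ]
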