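"""Notification response latency from social and communication apps.

When a social or communication app posts a notification, the phone logs an
OTHER app event for that package. The response latency is the time the
participant takes to unlock the phone after the notification. Notifications
arriving while the wearable indicates the participant is asleep are excluded
(they could not plausibly have been seen), and the retained latencies are
aggregated into per-day means and SDs — the two daily features analysed for
group differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .events import (
    AppCategory,
    AppEvent,
    AppEventType,
    PhoneState,
    PhoneStatusEvent,
    SleepInterval,
)
from .features import Feature, FeatureObservation

NOTIFICATION_CATEGORIES = (AppCategory.SOCIAL, AppCategory.COMMUNICATION)

#: Latencies above this are treated as unobserved responses (config default 24 h).
DEFAULT_LATENCY_CAP = 24.0 * 3600.0


@dataclass(frozen=True, slots=True)
class Notification:
    participant_id: str
    timestamp: float
    category: AppCategory


@dataclass(frozen=True, slots=True)
class NotificationResponse:
    participant_id: str
    notified_at: float
    responded_at: float
    category: AppCategory

    @property
    def latency(self) -> float:
        return self.responded_at - self.notified_at

    def __post_init__(self):
        if self.responded_at < self.notified_at:
            raise ValueError("response precedes notification")


def extract_notifications(
    app_events: Sequence[AppEvent],
    category_map: dict[str, AppCategory] | None = None,
) -> list[Notification]:
    """OTHER-type app events whose package is social or communication.

    If ``category_map`` is given it overrides the events' category field
    (packages absent from the map fall back to OTHER_CATEGORY); otherwise the
    category carried on each event is used.
    """
    out = []
    for e in app_events:
        if e.event_type is not AppEventType.OTHER:
            continue
        cat = category_map.get(e.package, AppCategory.OTHER_CATEGORY) if category_map is not None else e.category
        if cat in NOTIFICATION_CATEGORIES:
            out.append(Notification(e.participant_id, e.timestamp, cat))
    return out


def exclude_sleep(
    notifications: Sequence[Notification], sleep: Sequence[SleepInterval]
) -> list[Notification]:
    """Drop notifications delivered during a sleep interval (half-open [start, end)).

    Sleep intervals must be disjoint; overlap raises ValueError. Idempotent.
    """
    ivals = sorted(sleep, key=lambda s: s.start)
    for a, b in zip(ivals, ivals[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping sleep intervals at {b.start}")
    starts = np.array([s.start for s in ivals])
    ends = np.array([s.end for s in ivals])
    if not len(ivals):
        return list(notifications)
    times = np.array([n.timestamp for n in notifications])
    idx = np.searchsorted(starts, times, side="right") - 1
    asleep = (idx >= 0) & (times < ends[np.clip(idx, 0, None)])
    return [n for n, a in zip(notifications, asleep) if not a]


def match_unlock(
    notifications: Sequence[Notification],
    phone_status: Sequence[PhoneStatusEvent],
    latency_cap: float = DEFAULT_LATENCY_CAP,
    during_session_policy: str = "next_unlock",
    sessions=None,
) -> tuple[list[NotificationResponse], dict[str, int]]:
    """Pair each notification with the first UNLOCKED event strictly after it.

    Several pending notifications may share one unlock; each gets its own
    latency. Notifications with no subsequent unlock, or whose latency exceeds
    ``latency_cap`` seconds, are dropped and counted. ``during_session_policy``
    governs notifications arriving while the phone is already in active use
    (``sessions`` required for the non-default policies):

    - ``next_unlock`` (default): latency runs to the next unlock anyway;
    - ``zero``: the response is immediate (latency 0);
    - ``drop``: the notification is discarded (counted as ``in_session_dropped``).

    Returns the responses and a counter dict whose entries sum to the input
    count: ``matched + unmatched + over_cap (+ in_session_dropped)``.
    """
    if during_session_policy not in ("next_unlock", "zero", "drop"):
        raise ValueError(f"unknown during_session_policy {during_session_policy!r}")
    if during_session_policy != "next_unlock" and sessions is None:
        from .sessions import derive_sessions

        sessions = derive_sessions(phone_status)

    unlock_times = np.array(
        [e.timestamp for e in phone_status if e.state is PhoneState.UNLOCKED], dtype=float
    )
    if np.any(np.diff(unlock_times) < 0):
        raise ValueError("phone status events not sorted")
    times = np.array([n.timestamp for n in notifications], dtype=float)

    in_session = np.zeros(len(times), dtype=bool)
    if during_session_policy != "next_unlock" and sessions:
        s_starts = np.array([s.start for s in sessions])
        s_ends = np.array([s.end for s in sessions])
        idx = np.searchsorted(s_starts, times, side="right") - 1
        in_session = (idx >= 0) & (times < s_ends[np.clip(idx, 0, None)])

    pos = np.searchsorted(unlock_times, times, side="right")
    counters = {"matched": 0, "unmatched": 0, "over_cap": 0, "in_session_dropped": 0}
    responses = []
    for n, p, ins in zip(notifications, pos, in_session):
        if ins and during_session_policy == "drop":
            counters["in_session_dropped"] += 1
            continue
        if ins and during_session_policy == "zero":
            responses.append(NotificationResponse(n.participant_id, n.timestamp, n.timestamp, n.category))
            counters["matched"] += 1
            continue
        if p >= len(unlock_times):
            counters["unmatched"] += 1
            continue
        latency = unlock_times[p] - n.timestamp
        if latency > latency_cap:
            counters["over_cap"] += 1
            continue
        responses.append(
            NotificationResponse(n.participant_id, n.timestamp, float(unlock_times[p]), n.category)
        )
        counters["matched"] += 1
    return responses, counters


def local_day_index(t, enrollment_epoch: float, utc_offset_hours: float = 0.0):
    """Calendar day of ``t`` relative to the enrollment day, in the cohort's
    local time (fixed UTC offset)."""
    off = utc_offset_hours * 3600.0
    return np.floor((np.asarray(t) + off) / 86400.0) - np.floor((enrollment_epoch + off) / 86400.0)


def daily_latency_stats(
    responses: Sequence[NotificationResponse],
    enrollment_epoch: float,
    utc_offset_hours: float = 0.0,
    min_n: int = 2,
) -> list[FeatureObservation]:
    """Per participant-day mean and sample SD (n−1) of response latencies.

    Days with fewer than ``min_n`` responses emit nothing (default 2 so the SD
    exists). Emits one daily-mean and one daily-SD observation per retained
    participant-day.
    """
    if not responses:
        return []
    pid = responses[0].participant_id
    if any(r.participant_id != pid for r in responses):
        raise ValueError("daily_latency_stats expects a single participant")
    lat = np.array([r.latency for r in responses])
    days = local_day_index([r.notified_at for r in responses], enrollment_epoch, utc_offset_hours)
    obs = []
    for day in np.unique(days):
        values = lat[days == day]
        if len(values) < min_n:
            continue
        obs.append(
            FeatureObservation(Feature.NOTIFICATION_LATENCY_DAILY_MEAN, pid, float(np.mean(values)), float(day))
        )
        obs.append(
            FeatureObservation(Feature.NOTIFICATION_LATENCY_DAILY_SD, pid, float(np.std(values, ddof=1)), float(day))
        )
    return obs
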