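"""Active-App questionnaire features.

Participants receive pushed clinical questionnaires in three remote assessment
waves (~weeks 2, 6 and 10). From the notification / start / finish timestamps
we derive:

1. questionnaire notification response latency (hours, one value per started
   questionnaire — a repeated measure),
2. its SD pooled across all of a participant's questionnaires (one scalar per
   participant — the single time-aggregated feature, compared with a t-test),
3. the mean and 4. the SD of the interval between finishing one questionnaire
   and starting the next, computed within each wave (hours, one value per
   participant-wave).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .events import QuestionnaireRecord
from .features import Feature, FeatureObservation
from .notifications import local_day_index

log = logging.getLogger(__name__)

#: Questionnaires are available for 3 days after the notification; a start
#: recorded after that window is treated as never started.
DEFAULT_WINDOW_HOURS = 72.0


def _one_participant(records: Sequence[QuestionnaireRecord]) -> str:
    pids = {r.participant_id for r in records}
    if len(pids) != 1:
        raise ValueError(f"expected records for exactly one participant, got {sorted(pids)}")
    return pids.pop()


def questionnaire_latency(
    records: Sequence[QuestionnaireRecord],
    enrollment_epoch: float,
    utc_offset_hours: float = 0.0,
    window_hours: float = DEFAULT_WINDOW_HOURS,
) -> tuple[list[FeatureObservation], dict[str, int]]:
    """Hours from questionnaire notification to the participant starting it.

    Questionnaires never started (missing ``started_at``), or started after the
    availability window, yield no observation and are counted. The time index
    is the local day of the notification relative to enrollment, so the
    day-by-group interaction can be fitted on these observations.
    """
    if not records:
        return [], {"observed": 0, "never_started": 0, "over_window": 0}
    pid = _one_participant(records)
    obs = []
    counters = {"observed": 0, "never_started": 0, "over_window": 0}
    for r in records:
        if r.started_at is None:
            counters["never_started"] += 1
            continue
        hours = (r.started_at - r.notified_at) / 3600.0
        if hours > window_hours:
            counters["over_window"] += 1
            continue
        day = float(local_day_index(r.notified_at, enrollment_epoch, utc_offset_hours))
        obs.append(FeatureObservation(Feature.QUESTIONNAIRE_LATENCY, pid, hours, day))
        counters["observed"] += 1
    return obs, counters


def latency_sd_aggregate(
    latency_obs: Sequence[FeatureObservation],
) -> FeatureObservation | None:
    """Sample SD (n−1) of all of one participant's response latencies, pooled
    across waves. None (with a warning) when fewer than 2 observations exist."""
    values = [o.value for o in latency_obs if o.feature_id is Feature.QUESTIONNAIRE_LATENCY]
    if len(values) != len(latency_obs):
        raise ValueError("latency_sd_aggregate expects questionnaire-latency observations")
    if len(values) < 2:
        if latency_obs:
            log.warning(
                "participant %s has %d latency observation(s); SD aggregate omitted",
                latency_obs[0].participant_id, len(values),
            )
        return None
    pid = _one_participant(latency_obs)
    return FeatureObservation(
        Feature.QUESTIONNAIRE_LATENCY_SD, pid, float(np.std(values, ddof=1))
    )


def questionnaire_intervals(
    records: Sequence[QuestionnaireRecord],
    enrollment_epoch: float,
    utc_offset_hours: float = 0.0,
) -> list[FeatureObservation]:
    """Within-wave mean and SD of the gap between finishing one questionnaire
    and starting the next, in hours.

    Questionnaires are ordered by ``started_at`` within each wave; only
    completed ones (start and finish present) enter the chain. A negative gap
    (the next questionnaire started before the previous finished) is clipped
    to 0 with a warning. A wave needs >= 2 completed questionnaires for the
    mean and >= 3 (two gaps) for the sample SD.
    """
    if not records:
        return []
    pid = _one_participant(records)
    obs = []
    for wave in sorted({r.wave for r in records}):
        in_wave = [r for r in records if r.wave == wave]
        completed = sorted(
            (r for r in in_wave if r.started_at is not None and r.finished_at is not None),
            key=lambda r: r.started_at,
        )
        if len(completed) < 2:
            continue
        gaps = []
        for prev, nxt in zip(completed, completed[1:]):
            gap = (nxt.started_at - prev.finished_at) / 3600.0
            if gap < 0:
                log.warning("participant %s wave %d: overlapping questionnaires, gap clipped to 0", pid, wave)
                gap = 0.0
            gaps.append(gap)
        day = float(
            local_day_index(min(r.notified_at for r in in_wave), enrollment_epoch, utc_offset_hours)
        )
        obs.append(
            FeatureObservation(Feature.QUESTIONNAIRE_INTERVAL_MEAN, pid, float(np.mean(gaps)), day)
        )
        if len(gaps) >= 2:
            obs.append(
                FeatureObservation(Feature.QUESTIONNAIRE_INTERVAL_SD, pid, float(np.std(gaps, ddof=1)), day)
            )
    return obs
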