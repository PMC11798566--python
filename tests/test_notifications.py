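"""Notification extraction, sleep exclusion, unlock matching, daily stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digiphen.events import (
    AppCategory,
    AppEvent,
    AppEventType,
    PhoneState,
    PhoneStatusEvent,
    SleepInterval,
)
from digiphen.features import Feature
from digiphen.notifications import (
    Notification,
    daily_latency_stats,
    exclude_sleep,
    extract_notifications,
    match_unlock,
)

SOC, COM, OTH = AppCategory.SOCIAL, AppCategory.COMMUNICATION, AppCategory.OTHER_CATEGORY


def app(t, package="app.social.0", category=SOC, etype=AppEventType.OTHER):
    return AppEvent("p1", float(t), package, category, etype)


def unlocks(*ts):
    return [PhoneStatusEvent("p1", float(t), PhoneState.UNLOCKED) for t in ts]


def notifs(*ts, category=SOC):
    return [Notification("p1", float(t), category) for t in ts]


class TestExtract:
    def test_social_other_event_is_notification(self):
        assert extract_notifications([app(100)]) == notifs(100)

    def test_other_category_filtered(self):
        assert extract_notifications([app(100, "game", OTH)]) == []

    def test_mixed_stream_hand_count(self):
        events = [
            app(10, "app.social.0", SOC, AppEventType.OTHER),
            app(20, "game", OTH, AppEventType.OTHER),
            app(30, "app.comm.0", COM, AppEventType.OTHER),
            app(40, "game2", OTH, AppEventType.OTHER),
            app(50, "maps", OTH, AppEventType.OTHER),
            app(11, "app.social.0", SOC, AppEventType.FOREGROUND),
            app(31, "app.comm.0", COM, AppEventType.FOREGROUND),
            app(41, "game2", OTH, AppEventType.FOREGROUND),
        ]
        got = extract_notifications(events)
        assert [(n.timestamp, n.category) for n in got] == [(10.0, SOC), (30.0, COM)]

    def test_category_map_overrides_event_category(self):
        events = [app(100, "pkg.x", OTH)]
        got = extract_notifications(events, {"pkg.x": SOC})
        assert got == [Notification("p1", 100.0, SOC)]
        assert extract_notifications(events, {}) == []


class TestExcludeSleep:
    sleep = [SleepInterval("p1", 100.0, 200.0)]

    def test_inside_interval_removed(self):
        assert exclude_sleep(notifs(150), self.sleep) == []

    def test_boundary_is_half_open(self):
        assert exclude_sleep(notifs(200), self.sleep) == notifs(200)
        assert exclude_sleep(notifs(100), self.sleep) == []

    def test_hand_count(self):
        ns = notifs(10, 50, 110, 120, 210, 250, 300, 400, 500, 600)
        kept = exclude_sleep(ns, self.sleep)
        assert len(kept) == 8
        assert all(not (100 <= n.timestamp < 200) for n in kept)

    def test_idempotent(self):
        ns = notifs(10, 150, 250)
        once = exclude_sleep(ns, self.sleep)
        assert exclude_sleep(once, self.sleep) == once

    def test_overlapping_sleep_rejected(self):
        bad = [SleepInterval("p1", 0.0, 100.0), SleepInterval("p1", 50.0, 150.0)]
        with pytest.raises(ValueError, match="overlap"):
            exclude_sleep(notifs(10), bad)


class TestMatchUnlock:
    def test_first_subsequent_unlock(self):
        responses, counters = match_unlock(notifs(100), unlocks(90, 160))
        assert [r.latency for r in responses] == [60.0]
        assert counters == {"matched": 1, "unmatched": 0, "over_cap": 0, "in_session_dropped": 0}

    def test_shared_unlock(self):
        responses, _ = match_unlock(notifs(100, 110), unlocks(160))
        assert [r.latency for r in responses] == [60.0, 50.0]

    def test_after_last_unlock_dropped(self):
        responses, counters = match_unlock(notifs(200), unlocks(160))
        assert responses == []
        assert counters["unmatched"] == 1

    def test_over_cap_dropped_and_counted(self):
        responses, counters = match_unlock(notifs(0), unlocks(100.0), latency_cap=50.0)
        assert responses == []
        assert counters["over_cap"] == 1

    def test_counting_conservation(self):
        ns = notifs(0, 10, 500, 900, 2000)
        responses, counters = match_unlock(ns, unlocks(100, 600), latency_cap=200.0)
        assert counters["matched"] == len(responses)
        assert sum(counters.values()) == len(ns)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ts=st.lists(st.floats(0, 1e5), min_size=1, max_size=20),
        us=st.lists(st.floats(0, 1e5), min_size=1, max_size=20),
        delta=st.floats(0, 1e4),
    )
    def test_shifting_unlocks_shifts_latencies(self, ts, us, delta):
        """Delaying every unlock by delta increases a matched latency by
        exactly delta when the pairing is preserved (no other unlock slides
        into the (t − delta, t] window), and never by more."""
        us = sorted(us)
        base, _ = match_unlock(notifs(*sorted(ts)), unlocks(*us), latency_cap=np.inf)
        shifted, _ = match_unlock(
            notifs(*sorted(ts)), unlocks(*[u + delta for u in us]), latency_cap=np.inf
        )
        base_by_t = {r.notified_at: r.latency for r in base}
        for r in shifted:
            if r.notified_at not in base_by_t:
                continue
            expected = base_by_t[r.notified_at] + delta
            assert r.latency <= expected + 1e-6
            if not any(r.notified_at - delta < u <= r.notified_at for u in us):
                assert r.latency == pytest.approx(expected, abs=1e-6)

    def test_during_session_policies(self):
        status = [
            PhoneStatusEvent("p1", 0.0, PhoneState.UNLOCKED),
            PhoneStatusEvent("p1", 100.0, PhoneState.STANDBY),
            PhoneStatusEvent("p1", 300.0, PhoneState.UNLOCKED),
            PhoneStatusEvent("p1", 400.0, PhoneState.STANDBY),
        ]
        ns = notifs(50)  # during the first session
        next_unlock, _ = match_unlock(ns, status, during_session_policy="next_unlock")
        assert [r.latency for r in next_unlock] == [250.0]
        zero, _ = match_unlock(ns, status, during_session_policy="zero")
        assert [r.latency for r in zero] == [0.0]
        dropped, counters = match_unlock(ns, status, during_session_policy="drop")
        assert dropped == [] and counters["in_session_dropped"] == 1


class TestDailyStats:
    def _responses(self, latencies, day=0):
        out, _ = match_unlock(
            notifs(*[day * 86400.0 + 1000.0 * i for i in range(len(latencies))]),
            unlocks(*[day * 86400.0 + 1000.0 * i + lat for i, lat in enumerate(latencies)]),
        )
        return out

    def test_mean_and_sample_sd(self):
        obs = daily_latency_stats(self._responses([60.0, 120.0]), enrollment_epoch=0.0)
        by_feature = {o.feature_id: o.value for o in obs}
        assert by_feature[Feature.NOTIFICATION_LATENCY_DAILY_MEAN] == pytest.approx(90.0)
        assert by_feature[Feature.NOTIFICATION_LATENCY_DAILY_SD] == pytest.approx(42.426, abs=1e-3)

    def test_min_n_suppresses_single_response_days(self):
        assert daily_latency_stats(self._responses([60.0]), enrollment_epoch=0.0) == []

    def test_zero_variance_day(self):
        obs = daily_latency_stats(self._responses([30.0, 30.0, 30.0]), enrollment_epoch=0.0)
        sd = [o for o in obs if o.feature_id is Feature.NOTIFICATION_LATENCY_DAILY_SD]
        assert sd[0].value == 0.0

    def test_day_assignment_respects_utc_offset(self):
        responses = self._responses([10.0, 20.0], day=1)
        obs = daily_latency_stats(responses, enrollment_epoch=0.0, utc_offset_hours=0.0)
        assert {o.time_index for o in obs} == {1.0}
        # shifting local midnight by -3 h moves 01:00 events to the previous local day
        late_night = self._responses([10.0, 20.0])  # notified at 00:00, 00:16 UTC
        shifted = daily_latency_stats(late_night, enrollment_epoch=43200.0, utc_offset_hours=-3.0)
        assert {o.time_index for o in shifted} == {-1.0}
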