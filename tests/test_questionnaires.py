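"""Questionnaire response-latency and inter-questionnaire interval features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digiphen.events import QuestionnaireRecord
from digiphen.features import Feature
from digiphen.questionnaires import (
    latency_sd_aggregate,
    questionnaire_intervals,
    questionnaire_latency,
)

H = 3600.0


def rec(notified_h, started_h=None, finished_h=None, wave=1, name="q"):
    return QuestionnaireRecord(
        "p1",
        wave,
        name,
        notified_h * H,
        None if started_h is None else started_h * H,
        None if finished_h is None else finished_h * H,
    )


class TestLatency:
    def test_definition(self):
        obs, counters = questionnaire_latency([rec(10.0, 12.5, 13.0)], enrollment_epoch=0.0)
        assert obs[0].value == pytest.approx(2.5)
        assert obs[0].feature_id is Feature.QUESTIONNAIRE_LATENCY
        assert counters == {"observed": 1, "never_started": 0, "over_window": 0}

    def test_missing_start_skipped_and_counted(self):
        obs, counters = questionnaire_latency([rec(10.0)], enrollment_epoch=0.0)
        assert obs == []
        assert counters["never_started"] == 1

    def test_over_window_start_yields_no_observation(self):
        obs, counters = questionnaire_latency(
            [rec(0.0, 80.0, 81.0)], enrollment_epoch=0.0, window_hours=72.0
        )
        assert obs == []
        assert counters["over_window"] == 1

    def test_full_fixture_count(self):
        records = [
            rec(w * 100.0 + q, w * 100.0 + q + 1.0, w * 100.0 + q + 1.5, wave=w, name=f"q{q}")
            for w in (1, 2, 3)
            for q in range(5)
        ]
        obs, counters = questionnaire_latency(records, enrollment_epoch=0.0)
        assert len(obs) == 15
        assert counters["observed"] == 15

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        latencies=st.lists(st.floats(0.01, 70.0), min_size=1, max_size=10),
        shift_h=st.floats(0, 1000),
    )
    def test_clock_shift_invariance(self, latencies, shift_h):
        """Latency values do not change under a global clock shift."""
        def build(offset):
            return [
                rec(offset + 100.0 * i, offset + 100.0 * i + lat, offset + 100.0 * i + lat + 0.2)
                for i, lat in enumerate(latencies)
            ]

        base, _ = questionnaire_latency(build(0.0), enrollment_epoch=0.0)
        shifted, _ = questionnaire_latency(build(shift_h), enrollment_epoch=shift_h * H)
        assert [o.value for o in base] == pytest.approx([o.value for o in shifted])


class TestLatencySdAggregate:
    def _obs(self, latencies):
        records = [rec(100.0 * i, 100.0 * i + lat) for i, lat in enumerate(latencies)]
        return questionnaire_latency(records, enrollment_epoch=0.0)[0]

    def test_hand_computation(self):
        agg = latency_sd_aggregate(self._obs([2.0, 4.0, 6.0]))
        assert agg.value == pytest.approx(2.0)
        assert agg.feature_id is Feature.QUESTIONNAIRE_LATENCY_SD

    def test_zero_variance(self):
        assert latency_sd_aggregate(self._obs([3.0, 3.0, 3.0])).value == 0.0

    def test_single_observation_omitted(self):
        assert latency_sd_aggregate(self._obs([3.0])) is None

    def test_matches_flat_recomputation(self, rng):
        latencies = rng.gamma(2.0, 5.0, size=40).clip(0.01, 70.0)
        agg = latency_sd_aggregate(self._obs(list(latencies)))
        assert agg.value == pytest.approx(float(np.std(latencies, ddof=1)), rel=1e-9)


class TestIntervals:
    def test_hand_computation(self):
        # gaps of 0.1 h and 0.5 h between three completed questionnaires
        records = [
            rec(0.0, 1.0, 2.0),
            rec(0.0, 2.1, 3.0),
            rec(0.0, 3.5, 4.0),
        ]
        obs = questionnaire_intervals(records, enrollment_epoch=0.0)
        by_feature = {o.feature_id: o.value for o in obs}
        assert by_feature[Feature.QUESTIONNAIRE_INTERVAL_MEAN] == pytest.approx(0.3)
        assert by_feature[Feature.QUESTIONNAIRE_INTERVAL_SD] == pytest.approx(0.2828, abs=1e-4)

    def test_two_questionnaires_mean_only(self):
        records = [rec(0.0, 1.0, 2.0), rec(0.0, 2.5, 3.0)]
        obs = questionnaire_intervals(records, enrollment_epoch=0.0)
        assert [o.feature_id for o in obs] == [Feature.QUESTIONNAIRE_INTERVAL_MEAN]
        assert obs[0].value == pytest.approx(0.5)

    def test_back_to_back_zero_mean(self):
        records = [rec(0.0, 1.0, 2.0), rec(0.0, 2.0, 3.0)]
        obs = questionnaire_intervals(records, enrollment_epoch=0.0)
        assert obs[0].value == 0.0

    def test_single_completion_no_observation(self):
        assert questionnaire_intervals([rec(0.0, 1.0, 2.0), rec(0.0)], enrollment_epoch=0.0) == []

    def test_overlap_clipped_to_zero(self):
        records = [rec(0.0, 1.0, 3.0), rec(0.0, 2.5, 4.0)]  # starts before previous finished
        obs = questionnaire_intervals(records, enrollment_epoch=0.0)
        assert obs[0].value == 0.0

    def test_waves_are_independent(self):
        records = [rec(0.0, 1.0, 2.0), rec(0.0, 2.5, 3.0), rec(500.0, 501.0, 502.0, wave=2)]
        obs = questionnaire_intervals(records, enrollment_epoch=0.0)
        # wave 2 has a single completion: only wave 1 emits, and only the mean
        assert len(obs) == 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(gaps=st.lists(st.floats(0.0, 5.0), min_size=1, max_size=8))
    def test_gap_conservation(self, gaps):
        """mean gap × (k−1) equals the total elapsed gap time over k
        questionnaires."""
        start = 0.0
        records = []
        for i, gap in enumerate([0.0] + gaps):
            s = start + gap
            records.append(rec(0.0, s, s + 0.25, name=f"q{i}"))
            start = s + 0.25
        obs = questionnaire_intervals(records, enrollment_epoch=0.0)
        mean = next(o.value for o in obs if o.feature_id is Feature.QUESTIONNAIRE_INTERVAL_MEAN)
        assert mean * len(gaps) == pytest.approx(sum(gaps), abs=1e-6)
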