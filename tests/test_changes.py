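"""Change detection: aggregation, the 30% rule, attribution, emotions."""

import numpy as np
import pandas as pd
import pytest

from socialsurv.changes import (
    DailyCountSeries, DetectorConfig, EventRecord,
    InsufficientHistoryError, aggregate_daily, attribute_event,
    detect_change, detect_events, emotion_window,
)
from socialsurv.stream import EventInjection, StreamSpec, generate_stream, \
    generate_users


def _series(counts, region="R", topic="health", start="2020-01-01"):
    idx = pd.date_range(start, periods=len(counts), freq="D")
    return DailyCountSeries(region, topic, pd.Series(counts, index=idx))


class TestAggregateDaily:
    def test_single_day_count(self):
        df = pd.DataFrame({
            "region": ["R"] * 6, "topic": ["health"] * 6,
            "created_at": ["2020-01-01T10:00:00Z"] * 6,
        })
        (s,) = aggregate_daily(df)
        assert s.counts.tolist() == [6]

    def test_gap_days_zero_filled(self):
        df = pd.DataFrame({
            "region": ["R", "R"], "topic": ["t", "t"],
            "created_at": ["2020-01-01T10:00:00Z", "2020-01-03T10:00:00Z"],
        })
        (s,) = aggregate_daily(df)
        assert s.counts.tolist() == [1, 0, 1]

    def test_totals_conserved_across_splits(self, small_stream):
        _, _, messages, truth = small_stream
        topic_of = dict(zip(truth.message_id, truth.topic))
        df = pd.DataFrame({
            "region": [m["town"] for m in messages],
            "topic": [topic_of[m["id"]] for m in messages],
            "created_at": [m["created_at"] for m in messages],
        })
        series = aggregate_daily(df)
        assert sum(int(s.counts.sum()) for s in series) == len(messages)

    def test_bad_timestamps_rejected_with_warning(self):
        df = pd.DataFrame({
            "region": ["R", "R"], "topic": ["t", "t"],
            "created_at": ["2020-01-01T10:00:00Z", "not a date"],
        })
        with pytest.warns(UserWarning, match="unparseable"):
            (s,) = aggregate_daily(df)
        assert int(s.counts.sum()) == 1


class TestDetectChange:
    def test_step_from_15_to_30_flags_on_step_day(self):
        s = _series([15] * 10 + [30] * 3)
        flags = detect_change(s, DetectorConfig())
        assert flags[0].date == pd.Timestamp("2020-01-11")
        assert flags[0].direction == "increase"
        assert flags[0].relative_change == pytest.approx(1.0)

    def test_constant_series_never_flags(self):
        assert detect_change(_series([20] * 15), DetectorConfig()) == []

    def test_twenty_percent_change_below_threshold(self):
        s = _series([10] * 10 + [12] * 3)
        assert detect_change(s, DetectorConfig()) == []

    def test_fifty_percent_drop_flags_decrease(self):
        s = _series([20] * 10 + [10] * 2)
        flags = detect_change(s, DetectorConfig())
        assert flags[0].direction == "decrease"
        assert flags[0].relative_change == pytest.approx(-0.5)

    def test_day_over_day_mode(self):
        s = _series([10, 14, 14])
        flags = detect_change(s, DetectorConfig(mode="day-over-day"))
        assert len(flags) == 1 and flags[0].relative_change == \
            pytest.approx(0.4)

    def test_baseline_floor_suppresses_small_counts(self):
        s = _series([2] * 10 + [4] * 2)  # 100% change but baseline < 5
        assert detect_change(s, DetectorConfig()) == []

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientHistoryError):
            detect_change(_series([5] * 7), DetectorConfig(window=7))

    def test_deterministic(self):
        s = _series([15] * 10 + [30] * 3)
        assert detect_change(s) == detect_change(s)

    def test_larger_steps_flag_no_later(self):
        cfg = DetectorConfig()
        onset = {}
        for mult in (1.5, 2.0, 3.0, 5.0):
            s = _series([20] * 10 + [int(20 * mult)] * 4)
            onset[mult] = detect_change(s, cfg)[0].date
        dates = [onset[m] for m in (1.5, 2.0, 3.0, 5.0)]
        assert dates == sorted(dates, reverse=True) or len(set(dates)) == 1


class TestEvents:
    def test_consecutive_flags_merge_to_one_event(self):
        s = _series([15] * 10 + [30, 32, 31])
        events = detect_events([s])
        assert len(events) == 1
        assert events[0].onset == pd.Timestamp("2020-01-11")

    def test_attribution_dominant_subtopic(self):
        ev = EventRecord("R", "health", pd.Timestamp("2020-01-10"),
                         "increase", 0.5)
        msgs = pd.DataFrame({
            "created_at": ["2020-01-10T01:00:00Z"] * 35,
            "subtopic": ["flu"] * 30 + ["sport"] * 5,
            "tokens": [["flu", "bad"]] * 35,
        })
        attribute_event(ev, msgs)
        assert ev.dominant_subtopic == "flu" and not ev.subtopic_tie

    def test_attribution_tie_breaks_lexicographically(self):
        ev = EventRecord("R", "health", pd.Timestamp("2020-01-10"),
                         "increase", 0.5)
        msgs = pd.DataFrame({
            "created_at": ["2020-01-10T01:00:00Z"] * 20,
            "subtopic": ["flu"] * 10 + ["fever"] * 10,
            "tokens": [["x"]] * 20,
        })
        attribute_event(ev, msgs)
        assert ev.dominant_subtopic == "fever" and ev.subtopic_tie

    def test_keywords_ranked_by_frequency(self):
        ev = EventRecord("R", "health", pd.Timestamp("2020-01-10"),
                         "increase", 0.5)
        tokens = [["fever"]] * 40 + [["cough"]] * 10 + [["rest"]] * 5
        msgs = pd.DataFrame({
            "created_at": ["2020-01-10T01:00:00Z"] * 55,
            "subtopic": ["flu"] * 55,
            "tokens": tokens,
        })
        attribute_event(ev, msgs)
        assert ev.keywords[0] == "fever"

    def test_empty_window_rejected(self):
        ev = EventRecord("R", "health", pd.Timestamp("2020-06-01"),
                         "increase", 0.5)
        msgs = pd.DataFrame({
            "created_at": ["2020-01-01T01:00:00Z"],
            "subtopic": ["flu"], "tokens": [["x"]],
        })
        with pytest.raises(ValueError):
            attribute_event(ev, msgs)


class TestEmotionWindow:
    def _event(self, day="2020-01-16"):
        return EventRecord("R", "health", pd.Timestamp(day), "increase", 1.0)

    def test_each_emotion_normalized_to_unit_max(self):
        msgs = pd.DataFrame({
            "created_at": [f"2020-01-{d:02d}T01:00:00Z"
                           for d in range(1, 32)],
            "emotion": ["fear", "joy"] * 15 + ["fear"],
        })
        table = emotion_window(self._event(), msgs)
        assert table["fear"].max() == 1.0
        assert table.shape[0] == 31

    def test_absent_emotion_stays_zero_not_nan(self):
        msgs = pd.DataFrame({
            "created_at": ["2020-01-16T01:00:00Z"],
            "emotion": ["joy"],
        })
        with pytest.warns(UserWarning, match="truncated"):
            table = emotion_window(self._event(), msgs)
        assert not table.isna().any().any()

    def test_injected_fear_shift_raises_post_onset_mean(self):
        """Monte-Carlo over seeded replicates: an emotion shift that doubles
        fear after onset shows up as >= 1.5x the pre-onset normalized mean."""
        shift = {"anger": 0.10, "disgust": 0.08, "fear": 0.50,
                 "joy": 0.11, "sadness": 0.11, "surprise": 0.10}
        ratios = []
        for i in range(200):
            spec = StreamSpec(
                regions=["R"], users_per_region=10, topics=["health"],
                n_days=31, base_rate=2.0, seed=90_000 + i,
                events=[EventInjection("R", "health", "flu", 15, 16,
                                       rate_multiplier=1.0,
                                       emotion_shift=shift)])
            users, _ = generate_users(spec)
            msgs, truth = generate_stream(spec, users)
            frame = pd.DataFrame({
                "created_at": [m["created_at"] for m in msgs],
                "emotion": truth.emotion.values,
            })
            table = emotion_window(self._event(), frame)
            fear = table["fear"]
            before = fear.iloc[:15].mean()
            after = fear.iloc[16:].mean()
            if before > 0:
                ratios.append(after / before)
        mean_ratio = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert mean_ratio - 3 * se >= 1.5


def test_detector_no_later_than_two_day_confirmation_baseline():
    """On step changes the single-day rule flags no later than a naive
    detector that waits for two consecutive days above threshold."""
    def naive_onset(series, cfg=DetectorConfig()):
        flags = detect_change(series, cfg)
        days = [f.date for f in flags if f.direction == "increase"]
        for a, b in zip(days, days[1:]):
            if (b - a).days == 1:
                return b  # confirmed on the second consecutive day
        return None

    for mult in (1.5, 2.0, 3.0):
        s = _series([40] * 10 + [int(40 * mult)] * 5)
        ours = detect_events([s])[0].onset
        naive = naive_onset(s)
        assert naive is None or ours <= naive


def test_injection_recovery_and_false_alarms():
    """One 2x injected event per stream is recovered within a day; matched
    no-event streams stay quiet."""
    n_reps = 50
    hits = false_alarms = 0
    for i in range(n_reps):
        common = dict(regions=["R"], users_per_region=75, topics=["health"],
                      n_days=14, base_rate=2.0, seed=30_000 + i)
        ev = EventInjection("R", "health", "flu", start_day=10,
                           duration_days=4, rate_multiplier=2.0)
        for with_event in (True, False):
            spec = StreamSpec(**common, events=[ev] if with_event else [])
            users, _ = generate_users(spec)
            msgs, truth = generate_stream(spec, users)
            df = pd.DataFrame({
                "region": [m["town"] for m in msgs],
                "topic": "health",
                "created_at": [m["created_at"] for m in msgs],
            })
            events = detect_events(aggregate_daily(df))
            if with_event:
                if any(abs((e.onset - pd.Timestamp("2020-01-11")).days) <= 1
                       for e in events):
                    hits += 1
            else:
                false_alarms += bool(events)
    assert hits / n_reps >= 0.95
    assert false_alarms / n_reps <= 0.05
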