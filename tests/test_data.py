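"""Core data types and conversions: parsing, sampling conventions, round trips."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from behavts import (
    BinarySpikeTrain,
    EventRecord,
    EventSequence,
    IntervalSet,
    NominalTimeSeries,
    events_to_spike_train,
    events_to_timeseries,
    import_annotation_table,
    inter_onset_intervals,
    presence_resample,
    timeseries_to_events,
)
from behavts.data import parse_timestamp
from behavts.errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidInputError,
)
from conftest import oracle_presence


class TestTypes:
    def test_event_record_rejects_inverted_interval(self):
        with pytest.raises(InvalidInputError):
            EventRecord(2.0, 1.0, "a")
        with pytest.raises(InvalidInputError):
            EventRecord(1.0, 1.0, "a")

    def test_event_record_rejects_empty_code(self):
        with pytest.raises(InvalidInputError):
            EventRecord(0.0, 1.0, "")

    def test_sequence_sorts_and_detects_overlap(self):
        seq = EventSequence([EventRecord(2, 3, 1), EventRecord(0, 1, 2)])
        assert [r.onset for r in seq] == [0, 2]
        with pytest.raises(InvalidInputError):
            EventSequence([EventRecord(0, 2, 1), EventRecord(1, 3, 2)])
        # configurable
        EventSequence([EventRecord(0, 2, 1), EventRecord(1, 3, 2)], allow_overlap=True)

    def test_spike_train_codomain(self):
        with pytest.raises(InvalidInputError):
            BinarySpikeTrain([0, 1, 2], rate=1.0)

    def test_interval_set_statistics_use_sample_normalization(self):
        s = IntervalSet([1.0, 3.0])
        assert s.n == 2
        assert s.mean == 2.0
        assert s.std == pytest.approx(np.sqrt(2))
        with pytest.raises(InvalidInputError):
            IntervalSet([1.0, 0.0])


class TestTimestampParsing:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("2.5", 2.5),
            (7, 7.0),
            ("00:00:02.5", 2.5),
            ("01:02:03.25", 3723.25),
            ("02:30", 150.0),
        ],
    )
    def test_formats(self, raw, expected):
        assert parse_timestamp(raw) == pytest.approx(expected)

    def test_garbage_rejected(self):
        with pytest.raises(InvalidInputError):
            parse_timestamp("not a time")


class TestAnnotationImport:
    def test_basic_parse_with_label_encoding(self):
        rows = [("0.0", "1.5", "positive"), ("2.0", "3.0", "neutral")]
        seq = import_annotation_table(rows, encode_labels=True)
        assert len(seq) == 2
        assert all(isinstance(r.code, int) for r in seq)
        assert set(seq.code_labels.values()) == {"positive", "neutral"}

    def test_hms_timestamps(self):
        seq = import_annotation_table([("00:00:02.5", "00:00:04.0", "look")])
        assert len(seq) == 1
        rec = seq.records[0]
        assert (rec.onset, rec.offset, rec.code) == (2.5, 4.0, "look")

    def test_invalid_rows_excluded_and_counted(self, caplog):
        rows = [(0.0, 1.0, "a"), (5.0, 4.0, "b")]
        with caplog.at_level(logging.WARNING):
            seq = import_annotation_table(rows)
        assert len(seq) == 1
        assert seq.meta["dropped_invalid"] == 1

    def test_missing_fields_dropped_with_count(self):
        frame = pd.DataFrame(
            {"onset": [0.0, None], "offset": [1.0, 2.0], "code": ["a", "b"]}
        )
        seq = import_annotation_table(frame)
        assert len(seq) == 1
        assert seq.meta["dropped_missing"] == 1

    def test_unmappable_column_is_configuration_error(self):
        frame = pd.DataFrame({"start": [0], "stop": [1], "code": ["a"]})
        with pytest.raises(ConfigurationError):
            import_annotation_table(frame, column_map={"onset": "begin"})

    def test_epoch_timestamps_shifted_to_session_time(self):
        rows = [(1.6e9 + 5.0, 1.6e9 + 6.0, "a"), (1.6e9 + 1.5, 1.6e9 + 3.0, "b")]
        seq = import_annotation_table(rows)
        assert seq.records[0].onset == pytest.approx(0.0, abs=1e-6)
        assert seq.duration < 10


class TestEventsToTimeseries:
    def test_single_event_midpoint_rule(self):
        seq = EventSequence([EventRecord(0.0, 1.0, 3)])
        ts = events_to_timeseries(seq, rate=2, duration=2)
        assert ts.values.tolist() == [3, 3, 0, 0]

    def test_empty_sequence_background_fill(self):
        ts = events_to_timeseries(EventSequence([]), rate=4, duration=1)
        assert ts.values.tolist() == [0, 0, 0, 0]

    def test_midpoint_assignment_between_events(self):
        seq = EventSequence([EventRecord(0, 1, 3), EventRecord(1.5, 2, 2)])
        ts = events_to_timeseries(seq, rate=1, duration=2)
        assert ts.values.tolist() == [3, 2]

    def test_overlap_error_and_last_onset_wins(self):
        seq = EventSequence(
            [EventRecord(0, 2, 1), EventRecord(1, 3, 2)], allow_overlap=True
        )
        with pytest.raises(InvalidInputError):
            events_to_timeseries(seq, rate=1, duration=3)
        ts = events_to_timeseries(seq, rate=1, duration=3, last_onset_wins=True)
        assert ts.values.tolist() == [1, 2, 2]


class TestTimeseriesToEvents:
    def test_run_length_encoding(self):
        ts = NominalTimeSeries([3, 3, 0, 2], rate=1)
        seq = timeseries_to_events(ts)
        assert [(r.onset, r.offset, r.code) for r in seq] == [(0, 2, 3), (3, 4, 2)]

    def test_all_background_is_empty(self):
        assert len(timeseries_to_events(NominalTimeSeries([0, 0, 0], rate=2))) == 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=4),  # gap >= 1 sample
                st.integers(min_value=1, max_value=5),  # length in samples
                st.integers(min_value=1, max_value=4),  # code
            ),
            min_size=0,
            max_size=8,
        )
    )
    def test_round_trip_identity_on_sample_aligned_events(self, chunks):
        """events -> timeseries -> events recovers sample-aligned events."""
        t = 0
        records = []
        for gap, length, code in chunks:
            t += gap
            records.append(EventRecord(float(t), float(t + length), code))
            t += length
        seq = EventSequence(records)
        ts = events_to_timeseries(seq, rate=1)
        back = timeseries_to_events(ts)
        assert [(r.onset, r.offset, r.code) for r in back] == [
            (r.onset, r.offset, r.code) for r in seq
        ]

    def test_round_trip_preserves_covered_duration(self):
        seq = EventSequence([EventRecord(0.2, 1.7, 1), EventRecord(3.1, 4.0, 2)])
        ts = events_to_timeseries(seq, rate=10)
        back = timeseries_to_events(ts)
        covered = sum(r.duration for r in back)
        assert covered == pytest.approx(sum(r.duration for r in seq), abs=1 / 10)


class TestSpikeTrainConversion:
    def test_onsets_marked(self):
        seq = EventSequence([EventRecord(0.0, 0.5, 1), EventRecord(2.0, 2.5, 1)])
        train = events_to_spike_train(seq, rate=1, duration=4)
        assert train.values.tolist() == [1, 0, 1, 0]

    def test_empty_sequence_all_zero(self):
        train = events_to_spike_train(EventSequence([]), rate=2, duration=2)
        assert train.values.tolist() == [0, 0, 0, 0]

    def test_collision_collapses_to_single_spike(self, caplog):
        seq = EventSequence(
            [EventRecord(0.1, 0.15, 1), EventRecord(0.2, 0.3, 1)]
        )
        with caplog.at_level(logging.WARNING):
            train = events_to_spike_train(seq, rate=1, duration=1)
        assert train.values.tolist() == [1]
        # spike count = events - collisions
        assert train.n_onsets == len(seq) - 1

    def test_spike_count_equals_events_without_collisions(self, rng):
        onsets = np.cumsum(rng.integers(1, 10, size=30))
        seq = EventSequence(
            [EventRecord(float(t), float(t) + 0.5, 1) for t in onsets]
        )
        train = events_to_spike_train(seq, rate=1)
        assert train.n_onsets == len(seq)


class TestPresenceResample:
    def test_overlap_enumeration_example(self):
        seq = EventSequence([EventRecord(0.0, 0.5, "red")])
        trains = presence_resample(seq, 0.333, ["red"], duration=2.0)
        assert trains["red"].values.tolist()[:3] == [1, 1, 0]

    def test_event_inside_one_bin(self):
        seq = EventSequence([EventRecord(0.4, 0.6, 1)])
        trains = presence_resample(seq, 1.0, [1], duration=3.0)
        assert trains[1].values.sum() == 1

    def test_empty_code_filter_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            presence_resample(EventSequence([]), 0.333, [])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            t, records = 0.0, []
            for _ in range(int(rng.integers(1, 12))):
                t += float(rng.uniform(0.05, 2.0))
                dur = float(rng.uniform(0.05, 1.5))
                records.append((t, t + dur, int(rng.integers(1, 4))))
                t += dur
            seq = EventSequence([EventRecord(*r) for r in records])
            w = 0.333
            duration = seq.duration + 0.5
            trains = presence_resample(seq, w, [1, 2, 3], duration=duration)
            for code in (1, 2, 3):
                expected = oracle_presence(records, w, code, len(trains[code]))
                np.testing.assert_array_equal(trains[code].values, expected)


class TestInterOnsetIntervals:
    def test_regular_train(self):
        iois = inter_onset_intervals(BinarySpikeTrain([1, 0, 1, 0, 1], rate=1))
        assert iois.intervals.tolist() == [2.0, 2.0]
        assert (iois.n, iois.mean, iois.std) == (2, 2.0, 0.0)

    def test_hand_computed_statistics(self):
        iois = inter_onset_intervals(BinarySpikeTrain([1, 1, 0, 0, 1], rate=1))
        assert iois.intervals.tolist() == [1.0, 3.0]
        assert iois.std == pytest.approx(np.sqrt(2))

    def test_insufficient_onsets(self):
        with pytest.raises(InsufficientDataError):
            inter_onset_intervals(BinarySpikeTrain([0, 1, 0], rate=1))

    def test_interval_count_is_onsets_minus_one(self, rng):
        values = (rng.random(500) < 0.2).astype(int)
        train = BinarySpikeTrain(values, rate=2.0)
        assert inter_onset_intervals(train).n == train.n_onsets - 1
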