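"""Sensor-log / annotation / event / timeline I-O: round trips and validation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitcue import errors
from gaitcue.signal_model import (
    CueInterval,
    CueMode,
    CueReason,
    CueTimeline,
    EventKind,
    EventSequence,
    FogAnnotation,
    FootChannels,
    GaitEvent,
    Marker,
    MarkerKind,
    SensorLog,
    Side,
    read_annotations,
    read_cue_timeline,
    read_events,
    read_sensor_log,
    write_annotations,
    write_cue_timeline,
    write_events,
    write_sensor_log,
)


def make_log(n=5, fs=100.0, left_heel=None, markers=()):
    zeros = np.zeros(n, dtype=int)
    lh = np.asarray(left_heel) if left_heel is not None else zeros
    return SensorLog(
        sample_rate=fs,
        timestamps=np.arange(n) / fs,
        left=FootChannels(heel_lateral=lh, heel_medial=zeros.copy(), toe=zeros.copy()),
        right=FootChannels(heel_lateral=zeros.copy(), heel_medial=zeros.copy(), toe=zeros.copy()),
        markers=list(markers),
    )


class TestSensorLogValidation:
    def test_out_of_range_adc_rejected(self):
        with pytest.raises(errors.AdcRangeError):
            make_log(left_heel=[0, 1024, 0, 0, 0])

    def test_negative_adc_rejected(self):
        with pytest.raises(errors.AdcRangeError):
            make_log(left_heel=[0, -1, 0, 0, 0])

    def test_non_uniform_timestamps_rejected(self):
        ts = np.array([0.0, 0.01, 0.03])
        z = np.zeros(3, dtype=int)
        with pytest.raises(errors.NonMonotonicTimeError):
            SensorLog(
                sample_rate=100.0,
                timestamps=ts,
                left=FootChannels(z, z.copy(), z.copy()),
                right=FootChannels(z, z.copy(), z.copy()),
            )

    def test_duplicate_markers_rejected(self):
        ms = [Marker(0.0, MarkerKind.SEGMENT_START), Marker(0.01, MarkerKind.SEGMENT_START)]
        with pytest.raises(errors.UnknownMarkerError):
            make_log(markers=ms)

    def test_marker_order_enforced(self):
        ms = [Marker(0.02, MarkerKind.SEGMENT_START), Marker(0.01, MarkerKind.SEGMENT_END)]
        with pytest.raises(errors.UnknownMarkerError):
            make_log(markers=ms)

    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(errors.ChannelLengthError):
            FootChannels(np.zeros(3, int), np.zeros(2, int), np.zeros(3, int))


class TestSensorLogIO:
    def test_simple_parse(self, tmp_path):
        """A 3-row file with one supra-threshold heel sample parses directly."""
        p = tmp_path / "log.csv"
        write_sensor_log(make_log(n=3, left_heel=[0, 60, 0]), p)
        log = read_sensor_log(p)
        assert log.n_samples == 3
        assert list(log.left.heel_lateral) == [0, 60, 0]
        assert log.markers == []

    def test_out_of_range_value_in_file(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "# sample_rate_hz=100.0\n"
            "time_s,L_heel_lat,L_heel_med,L_toe,R_heel_lat,R_heel_med,R_toe,marker\n"
            "0.0,1024,0,0,0,0,0,\n"
        )
        with pytest.raises(errors.AdcRangeError):
            read_sensor_log(p)

    def test_missing_header_comment(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,L_heel_lat\n0.0,0\n")
        with pytest.raises(errors.MalformedHeaderError):
            read_sensor_log(p)

    def test_unknown_marker_kind(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "# sample_rate_hz=100.0\n"
            "time_s,L_heel_lat,L_heel_med,L_toe,R_heel_lat,R_heel_med,R_toe,marker\n"
            "0.0,0,0,0,0,0,0,lap_counter\n"
        )
        with pytest.raises(errors.UnknownMarkerError):
            read_sensor_log(p)

    def test_empty_log_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_sensor_log(make_log(n=0), p)
        lines = p.read_text().splitlines()
        assert len(lines) == 2  # comment + column header
        assert read_sensor_log(p).n_samples == 0

    def test_markers_written_in_time_order(self, tmp_path):
        ms = [Marker(0.01, MarkerKind.SEGMENT_START), Marker(0.03, MarkerKind.SEGMENT_END)]
        p = tmp_path / "m.csv"
        write_sensor_log(make_log(markers=ms), p)
        log = read_sensor_log(p)
        assert [m.kind for m in log.markers] == [MarkerKind.SEGMENT_START, MarkerKind.SEGMENT_END]
        assert [m.time for m in log.markers] == [0.01, 0.03]

    def test_off_grid_marker_rejected_on_write(self, tmp_path):
        log = make_log(markers=[Marker(0.0151, MarkerKind.SEGMENT_START)])
        with pytest.raises(errors.UnknownMarkerError):
            write_sensor_log(log, tmp_path / "x.csv")

    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(0, 40),
        fs=st.sampled_from([50.0, 100.0, 128.0]),
    )
    def test_round_trip_identity(self, tmp_path_factory, seed, n, fs):
        """write then read is the identity on randomly generated valid logs."""
        rng = np.random.default_rng(seed)
        chans = [rng.integers(0, 1024, size=n) for _ in range(6)]
        markers = []
        if n >= 2:
            markers = [
                Marker(0.0, MarkerKind.SEGMENT_START),
                Marker((n - 1) / fs, MarkerKind.SEGMENT_END),
            ]
        log = SensorLog(
            sample_rate=fs,
            timestamps=np.arange(n) / fs,
            left=FootChannels(*chans[:3]),
            right=FootChannels(*chans[3:]),
            markers=markers,
        )
        p = tmp_path_factory.mktemp("rt") / "log.csv"
        write_sensor_log(log, p)
        back = read_sensor_log(p)
        assert back.sample_rate == log.sample_rate
        assert np.array_equal(back.timestamps, log.timestamps)
        for side in ("left", "right"):
            for ch in ("heel_lateral", "heel_medial", "toe"):
                assert np.array_equal(getattr(getattr(back, side), ch), getattr(getattr(log, side), ch))
        assert back.markers == log.markers


class TestAnnotations:
    def test_two_disjoint_intervals(self, tmp_path):
        p = tmp_path / "a.csv"
        write_annotations(FogAnnotation([(1.0, 2.0), (5.0, 6.5)], source="clinician"), p)
        back = read_annotations(p)
        assert back.intervals == [(1.0, 2.0), (5.0, 6.5)]
        assert back.source == "clinician"

    def test_degenerate_interval_rejected(self):
        with pytest.raises(errors.InvalidIntervalError):
            FogAnnotation([(2.0, 2.0)])

    def test_degenerate_row_rejected_on_read(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("start_s,end_s,source\n3.0,3.0,clinician\n")
        with pytest.raises(errors.InvalidIntervalError):
            read_annotations(p)

    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0.001, 50)).map(
                lambda t: (round(t[0], 6), round(t[0] + t[1], 6))
            ),
            max_size=10,
        )
    )
    def test_round_trip(self, tmp_path_factory, intervals):
        intervals = [(s, e) for s, e in intervals if e > s]
        p = tmp_path_factory.mktemp("ann") / "a.csv"
        write_annotations(FogAnnotation(intervals, source="simulator"), p)
        assert read_annotations(p).intervals == intervals


class TestEventAndTimelineIO:
    def test_event_round_trip_and_labels(self, tmp_path):
        seq = EventSequence(
            [
                GaitEvent(EventKind.HEEL_STRIKE, Side.LEFT, 0.0),
                GaitEvent(EventKind.TOE_OFF, Side.RIGHT, 0.42),
            ]
        )
        assert [e.label for e in seq] == ["L+", "R-"]
        p = tmp_path / "e.csv"
        write_events(seq, p)
        back = read_events(p)
        assert back.events == seq.events

    def test_timeline_round_trip(self, tmp_path):
        tl = CueTimeline(
            mode=CueMode.ON_DEMAND,
            intervals=[
                CueInterval(1.0, 2.5, CueReason.TRIGGER_UPPER),
                CueInterval(4.0, 5.0, CueReason.TRIGGER_LOWER),
            ],
        )
        p = tmp_path / "t.csv"
        write_cue_timeline(tl, p)
        back = read_cue_timeline(p)
        assert back.mode == tl.mode and back.intervals == tl.intervals

    def test_empty_timeline_keeps_mode(self, tmp_path):
        p = tmp_path / "t.csv"
        write_cue_timeline(CueTimeline(mode=CueMode.NONE), p)
        back = read_cue_timeline(p)
        assert back.mode == CueMode.NONE and back.intervals == []

    def test_mode_invariants(self):
        with pytest.raises(errors.InvalidIntervalError):
            CueTimeline(mode=CueMode.NONE, intervals=[CueInterval(0, 1, CueReason.TRIGGER_UPPER)])
        with pytest.raises(errors.InvalidIntervalError):
            CueTimeline(mode=CueMode.CONTINUOUS, intervals=[])
        with pytest.raises(errors.InvalidIntervalError):
            CueTimeline(
                mode=CueMode.ON_DEMAND,
                intervals=[
                    CueInterval(0, 2, CueReason.TRIGGER_UPPER),
                    CueInterval(1, 3, CueReason.TRIGGER_UPPER),
                ],
            )
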