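"""Event/physio I/O, the closed action vocabulary, and stream normalization."""

from __future__ import annotations

import io
import json
import random

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import EP1, ev, sample
from vodwatch.events_io import (
    KIND_PRECEDENCE,
    ActionEvent,
    ActionKind,
    ContentRef,
    MarkerKind,
    normalize_events,
    parse_action_kind,
    parse_timestamp,
    read_action_log,
    read_physio_stream,
    write_action_log,
    write_export,
    write_physio_csv,
    write_marker_csv,
)


class TestVocabulary:
    def test_exactly_eleven_actions(self):
        assert len(ActionKind) == 11

    def test_precedence_covers_vocabulary(self):
        assert set(KIND_PRECEDENCE) == set(ActionKind)
        assert sorted(KIND_PRECEDENCE.values()) == list(range(11))

    @pytest.mark.parametrize("raw,expected", [
        ("play", ActionKind.PLAY),
        ("Skip Intro", ActionKind.SKIP_INTRO),
        ("session started", ActionKind.SESSION_START),
        ("SESSION-ENDED", ActionKind.SESSION_END),
    ])
    def test_kind_parsing_dialects(self, raw, expected):
        assert parse_action_kind(raw) is expected

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            parse_action_kind("zap")


class TestTimestamps:
    @pytest.mark.parametrize("raw,expected", [
        ("2019-06-01T22:00:00Z", 1559426400.0),
        ("2019-06-01T22:00:00+00:00", 1559426400.0),
        ("2019-06-02T00:00:00+02:00", 1559426400.0),  # zone converted at boundary
        (1559426400.5, 1559426400.5),
        ("1559426400.5", 1559426400.5),
    ])
    def test_parse(self, raw, expected):
        assert parse_timestamp(raw) == expected

    def test_unparsable_rejected(self):
        with pytest.raises(ValueError):
            parse_timestamp("yesterday evening")


class TestReadActionLog:
    def test_direct_field_mapping(self):
        line = json.dumps({
            "participant_id": "p1", "t": "2019-06-01T22:00:00Z", "kind": "play",
            "title_id": "A", "episode_id": "1", "media_pos_s": 0,
        })
        log = read_action_log(io.StringIO(line))
        assert not log.errors
        (e,) = log.events
        assert e.kind is ActionKind.PLAY
        assert e.media_pos_s == 0
        assert e.content == ContentRef("A", "1")

    def test_unknown_kind_collected_not_dropped(self):
        line = json.dumps({"participant_id": "p1", "t": 0, "kind": "zap"})
        log = read_action_log(io.StringIO(line))
        assert len(log.events) == 0 and len(log.errors) == 1
        assert "zap" in log.errors[0].message

    def test_twelve_line_fixture_with_one_malformed(self):
        lines = [json.dumps({"participant_id": "p1", "t": float(i), "kind": "play",
                             "title_id": "A"}) for i in range(11)]
        lines.insert(5, json.dumps({"participant_id": "p1", "t": "not a time",
                                    "kind": "play"}))
        log = read_action_log(io.StringIO("\n".join(lines)))
        assert len(log.events) == 11
        assert len(log.errors) == 1
        assert log.errors[0].line_no == 6

    def test_csv_dialect(self, tmp_path):
        path = tmp_path / "e.csv"
        events = [ev("SESSION_START", 0), ev("PLAY", 10, content=EP1, pos=0.0),
                  ev("SESSION_END", 100)]
        write_action_log(events, path, "csv")
        back = read_action_log(path, "csv")
        assert back.events == events and not back.errors


class TestPhysioStream:
    def _write(self, tmp_path, rows):
        path = tmp_path / "p.csv"
        header = "participant_id,device_id,t,hr_bpm,ax,ay,az,gx,gy,gz,battery_pct"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_clean_one_hz_fixture(self, tmp_path):
        rows = [f"p1,w1,{1000 + i},75,0,0,9.8,0,0,0,90" for i in range(10)]
        samples, markers = read_physio_stream(self._write(tmp_path, rows))
        assert len(samples) == 10
        assert all(not s.flags for s in samples)
        assert markers == []

    def test_out_of_range_hr_flagged_not_dropped(self, tmp_path):
        rows = ["p1,w1,1000,400,,,,,,,"]
        samples, _ = read_physio_stream(self._write(tmp_path, rows))
        assert len(samples) == 1
        assert "hr_out_of_range" in samples[0].flags
        assert samples[0].hr_bpm == 400

    def test_missing_mandatory_column_fatal(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant_id,t,hr_bpm\np1,0,70\n")
        with pytest.raises(ValueError, match="device_id"):
            read_physio_stream(path)

    def test_marker_sidecar(self, tmp_path):
        stream = self._write(tmp_path, ["p1,w1,1000,75,,,,,,,"])
        markers = tmp_path / "m.csv"
        markers.write_text(
            "participant_id,device_id,t,kind\np1,w1,990,watch_start\n")
        _, marker_list = read_physio_stream(stream, markers)
        assert len(marker_list) == 1
        assert marker_list[0].kind is MarkerKind.WATCH_START


class TestNormalize:
    def test_same_time_pair_reordered_by_precedence(self):
        out, notes = normalize_events([ev("PAUSE", 100), ev("PLAY", 100)])
        assert [e.kind for e in out] == [ActionKind.PLAY, ActionKind.PAUSE]
        assert [n.rule for n in notes] == ["same_time_reorder"]

    def test_already_ordered_is_identity(self):
        events = [ev("SESSION_START", 0), ev("PLAY", 10), ev("PAUSE", 50),
                  ev("SESSION_END", 60)]
        out, notes = normalize_events(events)
        assert out == events and notes == []

    def test_idempotent(self):
        events = [ev("PAUSE", 100), ev("PLAY", 100), ev("SESSION_START", 100)]
        once, _ = normalize_events(events)
        twice, notes = normalize_events(once)
        assert twice == once and notes == []

    def test_exact_duplicates_removed_with_note(self):
        e = ev("PLAY", 10, content=EP1, pos=0.0)
        out, notes = normalize_events([e, e, ev("PAUSE", 20, content=EP1, pos=10.0)])
        assert len(out) == 2
        assert [n.rule for n in notes] == ["duplicate_removed"]

    @pytest.mark.parametrize("shuffle_seed", range(5))
    def test_permutation_invariance(self, shuffle_seed):
        base = [ev(k, t, seq=i) for i, (k, t) in enumerate(
            [("SESSION_START", 0), ("PLAY", 10), ("FORWARD", 10), ("PAUSE", 10),
             ("PLAY", 30), ("PAUSE", 80), ("SESSION_END", 80)] * 7)]
        reference, _ = normalize_events(base)
        shuffled = list(base)
        random.Random(shuffle_seed).shuffle(shuffled)
        out, _ = normalize_events(shuffled)
        assert out == reference


_event_strategy = st.builds(
    ActionEvent,
    participant_id=st.sampled_from(["p1", "p2"]),
    t=st.integers(0, 10_000).map(lambda ms: ms / 1000 * 250),
    kind=st.sampled_from(list(ActionKind)),
    content=st.one_of(st.none(), st.just(EP1)),
    media_pos_s=st.one_of(st.none(), st.integers(0, 5000).map(float)),
    source_seq=st.one_of(st.none(), st.integers(0, 100)),
)


class TestRoundTrips:
    @given(st.lists(_event_strategy, max_size=30))
    def test_jsonl_round_trip_bit_exact(self, tmp_path_factory, events):
        path = tmp_path_factory.mktemp("rt") / "e.jsonl"
        write_action_log(events, path, "jsonl")
        back = read_action_log(path, "jsonl")
        assert back.events == events and not back.errors

    def test_physio_and_marker_round_trip(self, tmp_path):
        samples = [sample(1000 + i, battery=90.0 - i) for i in range(20)]
        from vodwatch.events_io import StreamMarker
        markers = [StreamMarker("p1", "w1", 995.0, MarkerKind.WATCH_START)]
        sp = write_physio_csv(samples, tmp_path / "p.csv")
        mp = write_marker_csv(markers, tmp_path / "m.csv")
        back_s, back_m = read_physio_stream(sp, mp)
        assert [ (s.participant_id, s.t, s.hr_bpm, s.battery_pct) for s in back_s ] \
            == [ (s.participant_id, s.t, s.hr_bpm, s.battery_pct) for s in samples ]
        assert back_m == markers


class TestWriteExport:
    def test_empty_table_header_only(self, tmp_path):
        paths = write_export({"t": pd.DataFrame(columns=["a", "b"])}, tmp_path)
        assert paths["t"].read_text().strip() == "a,b"

    def test_comma_field_quoted_and_round_trips(self, tmp_path):
        df = pd.DataFrame({"title": ["Comma, The Movie"], "n": [1]})
        paths = write_export({"t": df}, tmp_path)
        assert '"Comma, The Movie"' in paths["t"].read_text()
        back = pd.read_csv(paths["t"])
        pd.testing.assert_frame_equal(back, df)

    def test_hundred_row_round_trip(self, tmp_path):
        df = pd.DataFrame({"x": range(100), "y": [f"s{i}" for i in range(100)]})
        for fmt in ("csv", "json"):
            paths = write_export({"t": df}, tmp_path / fmt, format=fmt)
            back = (pd.read_csv(paths["t"]) if fmt == "csv"
                    else pd.read_json(paths["t"], orient="records"))
            pd.testing.assert_frame_equal(back, df)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_export({"t": pd.DataFrame()}, tmp_path, format="xlsx")
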