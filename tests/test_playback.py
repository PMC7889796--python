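"""Playback state machine: segments, wall↔media mapping, stamp repair."""

from __future__ import annotations

import math
import random

import pytest

from conftest import EP1, EP2, ev, sample
from oracles import media_position_at
from vodwatch.events_io import ActionKind, ContentRef, normalize_events
from vodwatch.playback import (
    PlayState,
    annotate_physio,
    build_timeline,
    map_wall_to_media,
    playing_intervals,
    repair_content_stamps,
)
from vodwatch.sessionize import build_sessions


def make_session(events, pid="p1"):
    """Segment and fully prepare a single session from raw events."""
    normalized, _ = normalize_events(events)
    result = build_sessions(normalized)
    assert len(result.sessions) == 1
    return result.sessions[0]


def play_pause_session():
    return make_session([
        ev("SESSION_START", 990),
        ev("PLAY", 1000, content=EP1, pos=0.0),
        ev("PAUSE", 1060, content=EP1, pos=60.0),
        ev("SESSION_END", 1100),
    ])


class TestBuildTimeline:
    def test_play_pause_end_segments(self):
        tl = build_timeline(play_pause_session())
        (a, b) = tl.segments
        assert (a.t0, a.t1, a.state, a.media_start, a.media_end) == \
            (1000, 1060, PlayState.PLAYING, 0.0, 60.0)
        assert (b.t0, b.t1, b.state, b.media_start, b.media_end) == \
            (1060, 1100, PlayState.PAUSED, 60.0, 60.0)
        assert tl.anomalies == []

    def test_episode_switch_closes_previous_segment(self):
        s = make_session([
            ev("SESSION_START", 0),
            ev("PLAY", 0, content=EP1, pos=0.0),
            ev("PLAY", 2400, content=EP2, pos=0.0),
            ev("PAUSE", 3000, content=EP2, pos=600.0),
            ev("SESSION_END", 3100),
        ])
        tl = build_timeline(s)
        first = tl.segments[0]
        assert first.content == EP1 and first.t1 == 2400 and first.media_end == 2400.0
        assert tl.segments[1].content == EP2 and tl.segments[1].media_start == 0.0

    def test_pause_before_play_is_anomaly_no_segment(self):
        s = make_session([ev("SESSION_START", 0), ev("PAUSE", 10, content=EP1, pos=5.0),
                          ev("SESSION_END", 60)])
        tl = build_timeline(s)
        assert tl.segments == []
        assert [a.kind for a in tl.anomalies] == ["pause_before_play"]

    def test_stamped_pause_position_wins_and_drift_recorded(self):
        s = make_session([
            ev("SESSION_START", 0),
            ev("PLAY", 0, content=EP1, pos=0.0),
            ev("PAUSE", 100, content=EP1, pos=250.0),  # projected 100
            ev("SESSION_END", 200),
        ])
        tl = build_timeline(s)
        assert [a.kind for a in tl.anomalies] == ["position_drift"]
        assert tl.segments[1].media_start == 250.0

    def test_seek_preserves_state_and_repositions(self):
        s = make_session([
            ev("SESSION_START", 0),
            ev("PLAY", 0, content=EP1, pos=0.0),
            ev("FORWARD", 50, content=EP1, pos=300.0),
            ev("PAUSE", 80, content=EP1, pos=330.0),
            ev("SESSION_END", 100),
        ])
        tl = build_timeline(s)
        states = [seg.state for seg in tl.segments]
        assert states == [PlayState.PLAYING, PlayState.PLAYING, PlayState.PAUSED]
        assert tl.segments[1].media_start == 300.0
        assert tl.anomalies == []

    def test_unstamped_skip_gives_unknown_media_still_playing(self):
        s = make_session([
            ev("SESSION_START", 0),
            ev("PLAY", 0, content=EP1, pos=0.0),
            ev("SKIP_INTRO", 20, content=EP1),  # no target position
            ev("SESSION_END", 100),
        ])
        tl = build_timeline(s)
        assert [a.kind for a in tl.anomalies] == ["unknown_seek_target"]
        unknown = tl.segments[1]
        assert unknown.state is PlayState.PLAYING and unknown.media_start is None
        assert playing_intervals(tl) == [(0, 100)]
        assert map_wall_to_media(tl, 50) is None


class TestMapWallToMedia:
    def test_linear_projection_inside_playing(self):
        tl = build_timeline(play_pause_session())
        assert map_wall_to_media(tl, 1030) == (EP1, 30.0)

    def test_frozen_position_inside_paused(self):
        tl = build_timeline(play_pause_session())
        assert map_wall_to_media(tl, 1080) == (EP1, 60.0)

    def test_outside_segments(self):
        tl = build_timeline(play_pause_session())
        assert map_wall_to_media(tl, 999) is None
        assert map_wall_to_media(tl, 1100) is None


class TestPlayingIntervals:
    def test_single_interval(self):
        assert playing_intervals(build_timeline(play_pause_session())) == [(1000, 1060)]

    def test_all_paused_after_initial_anomalous_pause(self):
        s = make_session([ev("SESSION_START", 0), ev("PAUSE", 10, content=EP1, pos=0.0),
                          ev("SESSION_END", 50)])
        assert playing_intervals(build_timeline(s)) == []

    def test_three_cycles_total_length(self):
        events = [ev("SESSION_START", 0)]
        expected = 0.0
        t = 0.0
        for _ in range(3):
            events.append(ev("PLAY", t, content=EP1, pos=0.0))
            events.append(ev("PAUSE", t + 100, content=EP1))
            expected += 100
            t += 150
        events.append(ev("SESSION_END", t))
        tl = build_timeline(make_session(events))
        ivals = playing_intervals(tl)
        assert len(ivals) == 3
        assert sum(b - a for a, b in ivals) == expected


class TestConservation:
    @pytest.mark.parametrize("seed", range(8))
    def test_playing_plus_paused_covers_first_play_to_end(self, seed):
        rng = random.Random(seed)
        events = [ev("SESSION_START", 0), ev("PLAY", 5, content=EP1, pos=0.0)]
        t = 5.0
        for _ in range(rng.randrange(1, 20)):
            t += rng.randrange(1, 120)
            kind = rng.choice(["PLAY", "PAUSE", "FORWARD", "REWIND",
                               "SKIP_INTRO", "SKIP_CREDITS"])
            events.append(ev(kind, t, content=EP1,
                             pos=float(rng.randrange(0, 2000))))
        t += rng.randrange(1, 60)
        events.append(ev("SESSION_END", t))
        s = make_session(events)
        tl = build_timeline(s)
        total = sum(seg.duration_s for seg in tl.segments)
        assert total == pytest.approx(s.effective_end_t - 5.0, abs=1e-9)
        # media never advances while paused, advances 1:1 while playing
        for seg in tl.segments:
            if seg.media_start is None:
                continue
            if seg.state is PlayState.PAUSED:
                assert seg.media_end == seg.media_start
            else:
                assert seg.media_end - seg.media_start == pytest.approx(seg.duration_s)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_per_second_replay_matches_interval_mapping(self, seed):
        rng = random.Random(100 + seed)
        events = [ev("SESSION_START", 0)]
        t = float(rng.randrange(1, 10))
        content = EP1
        events.append(ev("PLAY", t, content=content, pos=0.0))
        for _ in range(rng.randrange(0, 40)):
            t += rng.randrange(1, 90)
            kind = rng.choice(["PLAY", "PAUSE", "FORWARD", "REWIND", "PLAY"])
            if kind == "PLAY" and rng.random() < 0.3:
                content = EP2 if content == EP1 else EP1
            events.append(ev(kind, t, content=content,
                             pos=float(rng.randrange(0, 2400))))
        t += rng.randrange(1, 60)
        events.append(ev("SESSION_END", t))
        s = make_session(events)
        tl = build_timeline(s, drift_tol_s=math.inf)  # stamps always win anyway
        for k in range(0, int(s.effective_end_t) + 1):
            got = map_wall_to_media(tl, float(k))
            want = media_position_at(s.events, float(k)) \
                if k < s.effective_end_t else None
            if want is None:
                assert got is None, f"second {k}: {got} vs None"
            else:
                assert got is not None, f"second {k}: None vs {want}"
                assert got[0] == want[0]
                assert got[1] == pytest.approx(want[1], abs=1e-9)


class TestAnnotatePhysio:
    def test_samples_tagged_with_media_positions(self):
        tl = build_timeline(play_pause_session())
        samples = [sample(1000 + i) for i in range(60)]
        tagged = annotate_physio(tl, samples)
        assert len(tagged) == 60
        assert [m for _, _, m in tagged] == [float(i) for i in range(60)]

    def test_sample_outside_session_untagged(self):
        tl = build_timeline(play_pause_session())
        ((_, content, media),) = annotate_physio(tl, [sample(500)])
        assert content is None and media is None

    def test_empty_input(self):
        assert annotate_physio(build_timeline(play_pause_session()), []) == []


class TestRepairContentStamps:
    def test_empty_pause_inherits_following_episode(self):
        s = make_session([
            ev("SESSION_START", 0),
            ev("PLAY", 10, content=EP1, pos=0.0),
            ev("PAUSE", 2400),  # no content: the switch glitch
            ev("PLAY", 2403, content=EP2, pos=0.0),
            ev("SESSION_END", 3000),
        ])
        repaired, flags = repair_content_stamps(s)
        pause = [e for e in repaired.events if e.kind is ActionKind.PAUSE][0]
        assert pause.content == EP2
        assert [f.rule for f in flags] == ["empty_content_repaired"]
        assert flags[0].repaired

    def test_empty_event_far_from_neighbour_falls_back_to_state(self):
        s = make_session([
            ev("SESSION_START", 0),
            ev("PLAY", 10, content=EP1, pos=0.0),
            ev("PAUSE", 2400),
            ev("PLAY", 2500, content=EP2, pos=0.0),  # outside 10 s window
            ev("SESSION_END", 3000),
        ])
        repaired, flags = repair_content_stamps(s)
        pause = [e for e in repaired.events if e.kind is ActionKind.PAUSE][0]
        assert pause.content == EP1  # current state's content
        assert flags[0].repaired

    def test_stale_stamp_flagged_when_position_exceeds_runtime(self):
        s = make_session([
            ev("SESSION_START", 0),
            ev("PLAY", 10, content=EP1, pos=0.0),
            ev("PAUSE", 4010, content=EP1, pos=4000.0),  # runtime 2520
            ev("SESSION_END", 4100),
        ])
        _, flags = repair_content_stamps(s)
        assert [f.rule for f in flags] == ["stale_stamp"]

    def test_stale_stamp_reattributed_to_following_episode(self):
        s = make_session([
            ev("SESSION_START", 0),
            ev("PLAY", 10, content=EP1, pos=0.0),
            ev("PLAY", 2530, content=EP1, pos=2521.0),  # stale: past runtime
            ev("PAUSE", 2535, content=EP2, pos=5.0),
            ev("SESSION_END", 3000),
        ])
        repaired, flags = repair_content_stamps(s)
        stale_play = repaired.events[2]
        assert stale_play.content == EP2
        assert flags[0].rule == "stale_stamp" and flags[0].repaired

    def test_fully_stamped_stream_needs_no_repair(self):
        s = play_pause_session()
        repaired, flags = repair_content_stamps(s)
        assert flags == [] and repaired.events == s.events
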