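"""Playback timeline reconstruction: wall-clock ↔ media-time synchronization.

A session's in-player events drive a two-state machine (PLAYING / PAUSED)
whose output is a sequence of half-open wall-clock segments, each mapped to
an interval on the content's own timeline.  Playback rate is fixed at 1.0
(the action vocabulary has no speed control), so while PLAYING the media
position advances second-for-second with wall time, and while PAUSED it is
frozen.  Seeks and skips reposition instantaneously and preserve the
play/pause state.

The segments cover ``[first PLAY, effective_end)`` without holes, which
gives the conservation law used throughout the test suite:

    Σ playing wall time + Σ paused wall time = effective_end − first PLAY.

Event-stamped media positions are trusted over projections (the browser
extension read them from the player); a pause whose stamp disagrees with
the projected position by more than ``drift_tol_s`` wins and the drift is
recorded as an anomaly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .events_io import ActionEvent, ActionKind, ContentRef, PhysioSample
from .sessionize import Session

__all__ = [
    "PlayState",
    "PlaybackSegment",
    "Anomaly",
    "Timeline",
    "RepairFlag",
    "build_timeline",
    "map_wall_to_media",
    "playing_intervals",
    "annotate_physio",
    "repair_content_stamps",
    "DRIFT_TOL_S",
    "REPAIR_WINDOW_S",
]

#: Tolerated disagreement (s) between a pause's stamped media position and
#: the position projected from the running segment before a drift anomaly
#: is raised.
DRIFT_TOL_S = 2.0

#: How far ahead (s) a content-less event may look for a content-bearing
#: neighbour when repairing empty stamps at episode switches.
REPAIR_WINDOW_S = 10.0

_SEEK_KINDS = (ActionKind.FORWARD, ActionKind.REWIND,
               ActionKind.SKIP_INTRO, ActionKind.SKIP_CREDITS)


class PlayState(Enum):
    PLAYING = "playing"
    PAUSED = "paused"


@dataclass(frozen=True)
class PlaybackSegment:
    """A wall-clock interval in one playback state on one content item.

    ``media_start`` is None when the position is unknown (e.g. a skip with
    no stamped target): such seconds still count as wall time in their
    state but are excluded from media mapping.
    """

    content: ContentRef | None
    state: PlayState
    t0: float
    t1: float
    media_start: float | None

    def __post_init__(self) -> None:
        if not self.t0 < self.t1:
            raise ValueError("segment wall interval must be non-empty")

    @property
    def duration_s(self) -> float:
        return self.t1 - self.t0

    @property
    def media_end(self) -> float | None:
        if self.media_start is None:
            return None
        if self.state is PlayState.PLAYING:
            return self.media_start + self.duration_s
        return self.media_start

    def media_at(self, t: float) -> float | None:
        """Media position at wall time t ∈ [t0, t1)."""
        if self.media_start is None:
            return None
        if self.state is PlayState.PLAYING:
            return self.media_start + (t - self.t0)
        return self.media_start


@dataclass(frozen=True)
class Anomaly:
    kind: str
    t: float
    message: str


@dataclass
class Timeline:
    session_id: str
    segments: list[PlaybackSegment] = field(default_factory=list)
    anomalies: list[Anomaly] = field(default_factory=list)

    @property
    def first_play_t(self) -> float | None:
        return self.segments[0].t0 if self.segments else None


@dataclass(frozen=True)
class RepairFlag:
    """Audit record of a content-stamp repair (or an unrepairable stamp)."""

    rule: str  # "empty_content_repaired" | "empty_content_unrepaired" | "stale_stamp"
    t: float
    kind: ActionKind
    detail: str
    repaired: bool


class _MachineState:
    __slots__ = ("state", "content", "media", "seg_t0")

    def __init__(self) -> None:
        self.state: PlayState | None = None  # None = no content yet
        self.content: ContentRef | None = None
        self.media: float | None = None  # position at seg_t0
        self.seg_t0: float = 0.0


def build_timeline(session: Session, drift_tol_s: float = DRIFT_TOL_S) -> Timeline:
    """Run the playback state machine over a session's events.

    State transitions: PLAY opens (or re-opens) a PLAYING segment at the
    stamped position, closing whatever was open — including the previous
    episode's segment on an episode switch; PAUSE freezes; seeks/skips
    reposition without changing state.  The open segment is closed at the
    session's effective end.  A PAUSE before any PLAY yields an anomaly and
    no segment.
    """
    if session.effective_end_t is None:
        raise ValueError("build_timeline requires effective_end_t")
    tl = Timeline(session_id=session.session_id)
    st = _MachineState()
    end = session.effective_end_t

    def close(t1: float) -> None:
        """Close the open segment at t1 and move the origin forward."""
        if st.state is None:
            st.seg_t0 = t1
            return
        if t1 > st.seg_t0:
            tl.segments.append(PlaybackSegment(
                content=st.content, state=st.state,
                t0=st.seg_t0, t1=t1, media_start=st.media,
            ))
            if st.state is PlayState.PLAYING and st.media is not None:
                st.media = st.media + (t1 - st.seg_t0)
        st.seg_t0 = t1

    for e in session.events:
        if e.kind not in (ActionKind.PLAY, ActionKind.PAUSE, *_SEEK_KINDS):
            continue
        if e.t > end:
            tl.anomalies.append(Anomaly("event_after_effective_end", e.t,
                                        f"{e.kind.value} after effective end"))
            continue
        if e.kind is ActionKind.PLAY:
            close(e.t)
            same_content = (e.content is None or st.content is None
                            or e.content == st.content)
            if e.media_pos_s is not None:
                media = e.media_pos_s
            elif same_content:
                media = st.media  # resume from the frozen/projected position
            else:
                media = None
                tl.anomalies.append(Anomaly("missing_media_position", e.t,
                                            "play on new content without a position"))
            st.state = PlayState.PLAYING
            if e.content is not None:
                st.content = e.content
            st.media = media
        elif e.kind is ActionKind.PAUSE:
            if st.state is None:
                tl.anomalies.append(Anomaly("pause_before_play", e.t,
                                            "pause with no prior play"))
                continue
            projected = None
            if st.state is PlayState.PLAYING and st.media is not None:
                projected = st.media + (e.t - st.seg_t0)
            close(e.t)
            if e.media_pos_s is not None:
                if projected is not None and abs(e.media_pos_s - projected) > drift_tol_s:
                    tl.anomalies.append(Anomaly(
                        "position_drift", e.t,
                        f"stamped {e.media_pos_s:.1f}s vs projected {projected:.1f}s",
                    ))
                st.media = e.media_pos_s
            st.state = PlayState.PAUSED
            if e.content is not None:
                st.content = e.content
        else:  # seek / skip: instantaneous reposition, state preserved
            if st.state is None:
                tl.anomalies.append(Anomaly("seek_before_play", e.t,
                                            f"{e.kind.value} with no prior play"))
                continue
            close(e.t)
            st.media = e.media_pos_s  # post-jump position; None = unknown target
            if e.media_pos_s is None:
                tl.anomalies.append(Anomaly("unknown_seek_target", e.t,
                                            f"{e.kind.value} without a stamped position"))
            if e.content is not None:
                st.content = e.content

    close(end)
    return tl


def map_wall_to_media(timeline: Timeline, t: float) -> tuple[ContentRef, float] | None:
    """Content identity and media position at wall time t, if determinable.

    Returns None outside all segments, and inside segments whose content or
    media origin is unknown.
    """
    starts = [seg.t0 for seg in timeline.segments]
    i = bisect.bisect_right(starts, t) - 1
    if i < 0:
        return None
    seg = timeline.segments[i]
    if not (seg.t0 <= t < seg.t1):
        return None
    m = seg.media_at(t)
    if seg.content is None or m is None:
        return None
    return seg.content, m


def playing_intervals(timeline: Timeline) -> list[tuple[float, float]]:
    """Union of wall intervals spent PLAYING: disjoint, sorted, merged."""
    out: list[tuple[float, float]] = []
    for seg in timeline.segments:
        if seg.state is not PlayState.PLAYING:
            continue
        if out and out[-1][1] == seg.t0:
            out[-1] = (out[-1][0], seg.t1)
        else:
            out.append((seg.t0, seg.t1))
    return out


def annotate_physio(
    timeline: Timeline, samples: Sequence[PhysioSample]
) -> list[tuple[PhysioSample, ContentRef | None, float | None]]:
    """Tag each sample with the content and media position it was watched at.

    Sample count and order are preserved; samples outside playback get
    ``(sample, None, None)``.
    """
    out = []
    for s in samples:
        hit = map_wall_to_media(timeline, s.t)
        if hit is None:
            out.append((s, None, None))
        else:
            out.append((s, hit[0], hit[1]))
    return out


def repair_content_stamps(
    session: Session, repair_window_s: float = REPAIR_WINDOW_S
) -> tuple[Session, list[RepairFlag]]:
    """Repair the two episode-switch stamping faults seen in the wild.

    1. *Empty content*: the extension was sometimes too slow to read the new
       episode's identity, leaving pause/play events with no content.  Such
       an event during active playback inherits the content of the nearest
       following content-bearing event within ``repair_window_s``; failing
       that, the content of the current playback state; failing that it
       stays empty and is flagged.
    2. *Stale stamp*: an event whose stamped media position exceeds its
       episode's known runtime must carry the previous episode's frame of
       reference; it is flagged, and its content replaced by the next
       episode's when one follows within the window.

    Every repair is recorded in the returned flags; nothing is silent.
    """
    events = list(session.events)
    flags: list[RepairFlag] = []
    new_events: list[ActionEvent] = []
    current_content: ContentRef | None = None
    playback_active = False

    content_events = [(e.t, i) for i, e in enumerate(events) if e.content is not None]

    def next_content_within(i: int, t: float) -> ContentRef | None:
        for ct, j in content_events:
            if j > i and 0 <= ct - t <= repair_window_s:
                return events[j].content
            if ct - t > repair_window_s:
                break
        return None

    for i, e in enumerate(events):
        out = e
        is_player_event = e.kind in (ActionKind.PLAY, ActionKind.PAUSE, *_SEEK_KINDS)
        if is_player_event and e.content is None and playback_active:
            inherited = next_content_within(i, e.t) or current_content
            if inherited is not None:
                out = replace(e, content=inherited)
                flags.append(RepairFlag(
                    rule="empty_content_repaired", t=e.t, kind=e.kind,
                    detail=f"attributed to {inherited.title_id}"
                           f"/{inherited.episode_id or '-'}",
                    repaired=True,
                ))
            else:
                flags.append(RepairFlag(
                    rule="empty_content_unrepaired", t=e.t, kind=e.kind,
                    detail="no content-bearing neighbour", repaired=False,
                ))
        elif (
            is_player_event
            and out.content is not None
            and out.content.runtime_s is not None
            and out.media_pos_s is not None
            and out.media_pos_s > out.content.runtime_s
        ):
            replacement = next_content_within(i, e.t)
            stale = out.content
            if replacement is not None and replacement != stale:
                out = replace(out, content=replacement)
                flags.append(RepairFlag(
                    rule="stale_stamp", t=e.t, kind=e.kind,
                    detail=f"position {e.media_pos_s:.0f}s exceeds runtime "
                           f"{stale.runtime_s:.0f}s; reattributed to "
                           f"{replacement.title_id}/{replacement.episode_id or '-'}",
                    repaired=True,
                ))
            else:
                flags.append(RepairFlag(
                    rule="stale_stamp", t=e.t, kind=e.kind,
                    detail=f"position {e.media_pos_s:.0f}s exceeds runtime "
                           f"{stale.runtime_s:.0f}s",
                    repaired=False,
                ))
        if e.kind is ActionKind.PLAY:
            playback_active = True
        if out.content is not None and is_player_event:
            current_content = out.content
        new_events.append(out)

    repaired = replace_session_events(session, tuple(new_events))
    return repaired, flags


def replace_session_events(session: Session, events: tuple[ActionEvent, ...]) -> Session:
    """Copy a session with a new event tuple (classification etc. kept)."""
    s = Session(
        session_id=session.session_id, participant_id=session.participant_id,
        start_t=session.start_t, observed_end_t=session.observed_end_t,
        events=events, classification=session.classification,
        effective_end_t=session.effective_end_t,
        watch_start_t=session.watch_start_t, flags=session.flags,
    )
    return s
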