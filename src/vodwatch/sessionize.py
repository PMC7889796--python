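"""Segment normalized event streams into viewing sessions and classify them.

A session spans from the tab-open boundary marker (``SESSION_START``) to the
tab-close marker (``SESSION_END``).  Three classes cover the field reality:

* **VALID** — content was played and both boundaries were observed.
* **SEMI_VALID** — content was played but the close was never recorded
  (the viewer left the tab open, sometimes for days); the effective end is
  imputed from the last pause / stop-playing action.
* **EMPTY** — boundaries observed but no content played (login attempts,
  browsing only).

The class partition is exhaustive: every segmented session receives exactly
one of the three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .events_io import (
    ActionEvent,
    ActionKind,
    MarkerKind,
    PhysioSample,
    StreamMarker,
)

__all__ = [
    "SessionClass",
    "Session",
    "SegmentationResult",
    "make_session_id",
    "segment_sessions",
    "classify_session",
    "impute_effective_end",
    "attach_watch_start",
    "build_sessions",
]

#: Look-back window (s) for inferring a missing watch-start from the first
#: physiological sample.  Bounded so that a session recorded without the
#: watch does not inherit a stale stream from hours earlier.
WATCH_FALLBACK_LOOKBACK_S = 600.0


class SessionClass(Enum):
    VALID = "valid"
    SEMI_VALID = "semi_valid"
    EMPTY = "empty"


def make_session_id(participant_id: str, start_t: float) -> str:
    """Stable session identifier: participant plus millisecond start time.

    The id is the join key for everything downstream (coverage, QA,
    questionnaire linkage), so it must be a pure function of the session.
    """
    return f"{participant_id}:{round(start_t * 1000)}"


@dataclass
class Session:
    """A reconstructed viewing session."""

    session_id: str
    participant_id: str
    start_t: float
    observed_end_t: float | None
    events: tuple[ActionEvent, ...]
    classification: SessionClass | None = None
    effective_end_t: float | None = None
    watch_start_t: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def has_content(self) -> bool:
        """True when at least one PLAY event was recorded.

        Searching/browsing without playing does not count: browsing-only
        sessions are the natural open-and-close behaviour of users and are
        classified EMPTY.
        """
        return any(e.kind is ActionKind.PLAY for e in self.events)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def add_flag(self, flag: str) -> None:
        if flag not in self.flags:
            self.flags = self.flags + (flag,)


@dataclass
class SegmentationResult:
    sessions: list[Session]
    stray_events: list[ActionEvent] = field(default_factory=list)

    def __iter__(self):
        return iter(self.sessions)


def segment_sessions(events: Sequence[ActionEvent]) -> SegmentationResult:
    """Bracket-match SESSION_START/SESSION_END per participant.

    Rules, in order of precedence:

    * a SESSION_END closes the open session of its participant;
    * a SESSION_START while a session is open force-closes the earlier one
      as unclosed (semi-valid candidate) — one participant cannot have two
      overlapping sessions;
    * an orphan SESSION_END (no open session) yields a degenerate
      zero-event session flagged ``orphan_session_end``;
    * events outside any session are returned as stray, never attached.

    Input must already be normalized (sorted, de-duplicated).
    """
    by_participant: dict[str, list[ActionEvent]] = {}
    for e in events:
        by_participant.setdefault(e.participant_id, []).append(e)

    sessions: list[Session] = []
    stray: list[ActionEvent] = []
    for pid in by_participant:
        open_start: float | None = None
        open_events: list[ActionEvent] = []
        for e in by_participant[pid]:
            if e.kind is ActionKind.SESSION_START:
                if open_start is not None:
                    s = Session(
                        session_id=make_session_id(pid, open_start),
                        participant_id=pid, start_t=open_start,
                        observed_end_t=None, events=tuple(open_events),
                    )
                    s.add_flag("force_closed_by_next_start")
                    sessions.append(s)
                open_start = e.t
                open_events = [e]
            elif e.kind is ActionKind.SESSION_END:
                if open_start is None:
                    s = Session(
                        session_id=make_session_id(pid, e.t),
                        participant_id=pid, start_t=e.t,
                        observed_end_t=e.t, events=(),
                    )
                    s.add_flag("orphan_session_end")
                    sessions.append(s)
                else:
                    open_events.append(e)
                    sessions.append(Session(
                        session_id=make_session_id(pid, open_start),
                        participant_id=pid, start_t=open_start,
                        observed_end_t=e.t, events=tuple(open_events),
                    ))
                    open_start = None
                    open_events = []
            else:
                if open_start is None:
                    stray.append(e)
                else:
                    open_events.append(e)
        if open_start is not None:
            sessions.append(Session(
                session_id=make_session_id(pid, open_start),
                participant_id=pid, start_t=open_start,
                observed_end_t=None, events=tuple(open_events),
            ))
    sessions.sort(key=lambda s: (s.participant_id, s.start_t))
    return SegmentationResult(sessions=sessions, stray_events=stray)


def classify_session(session: Session) -> SessionClass:
    """Assign one of the three session classes.

    The unnamed corner "no content and no observed close" is folded into
    EMPTY (callers flag it); it is not a fourth class.
    """
    if session.has_content:
        return SessionClass.VALID if session.observed_end_t is not None else SessionClass.SEMI_VALID
    return SessionClass.EMPTY


_PLAYBACK_KINDS = (ActionKind.PLAY, ActionKind.PAUSE)


def impute_effective_end(session: Session) -> float:
    """The session end used by every coverage window.

    With an observed close, that close is the end.  Without one
    (semi-valid), the end is the last pause — unless the stream ends
    mid-play, in which case the last event of any kind stands in (callers
    flag the substitution).
    """
    if session.observed_end_t is not None:
        return session.observed_end_t
    if not session.events:
        return session.start_t
    playback = [e for e in session.events if e.kind in _PLAYBACK_KINDS]
    if playback and playback[-1].kind is ActionKind.PAUSE:
        return playback[-1].t
    return session.events[-1].t


def attach_watch_start(
    session: Session,
    markers: Sequence[StreamMarker] = (),
    samples: Sequence[PhysioSample] = (),
    lookback_s: float = WATCH_FALLBACK_LOOKBACK_S,
) -> Session:
    """Resolve when the participant pressed Start on the smartwatch.

    Preference order: the latest WATCH_START marker at or before the
    effective end; failing that, the first physiological sample within
    ``[start − lookback_s, effective_end)``; failing both, unset (the
    transmission-window metrics are then reported as missing).
    Requires effective_end_t to be set.
    """
    if session.effective_end_t is None:
        raise ValueError("attach_watch_start requires effective_end_t")
    end = session.effective_end_t
    starts = [
        m.t for m in markers
        if m.kind is MarkerKind.WATCH_START
        and m.participant_id == session.participant_id and m.t <= end
    ]
    if starts:
        session.watch_start_t = max(starts)
        return session
    lo = session.start_t - lookback_s
    in_window = [
        s.t for s in samples
        if s.participant_id == session.participant_id and lo <= s.t < end
    ]
    if in_window:
        session.watch_start_t = min(in_window)
        session.add_flag("watch_start_inferred_from_samples")
    return session


def build_sessions(
    events: Sequence[ActionEvent],
    markers: Sequence[StreamMarker] = (),
    samples: Sequence[PhysioSample] = (),
    lookback_s: float = WATCH_FALLBACK_LOOKBACK_S,
) -> SegmentationResult:
    """Segment, classify, impute ends and attach watch starts in one pass."""
    result = segment_sessions(events)
    for s in result.sessions:
        s.classification = classify_session(s)
        if s.classification is SessionClass.EMPTY and s.observed_end_t is None:
            s.add_flag("empty_unclosed")
        s.effective_end_t = impute_effective_end(s)
        if s.classification is SessionClass.SEMI_VALID:
            playback = [e for e in s.events if e.kind in _PLAYBACK_KINDS]
            if not playback or playback[-1].kind is not ActionKind.PAUSE:
                s.add_flag("no_terminating_pause")
            inner = [e for e in s.events
                     if e.kind not in (ActionKind.SESSION_START, ActionKind.SESSION_END)]
            if len(inner) == 1 and inner[0].kind is ActionKind.PLAY:
                s.add_flag("degenerate_single_play")
        attach_watch_start(s, markers, samples, lookback_s=lookback_s)
    return result
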