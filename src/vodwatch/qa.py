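"""Quality-assurance rules and alarms over reconstructed study data.

Each rule reproduces, as an offline re-check, a failure detector that
originally ran live during data collection: coherence of the action
sequence, the five-second pre-session presence check, the periodic
every-five-minutes stream verification, the low-battery alert, and
terminal-dropout detection.  Rules only *report*: repairs happen in the
modules that own the data (normalization in events_io, stamp repair in
playback) and surface here as ``repaired`` findings.

Findings are deterministic for a fixed input and ordered by
(session, time, rule id), so two runs over the same bundle are identical.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .coverage import CoverageReport
from .events_io import ActionEvent, ActionKind, NormalizationNote, PhysioSample
from .playback import RepairFlag, Timeline
from .sessionize import Session

__all__ = [
    "Severity",
    "QAFinding",
    "QAResult",
    "check_coherence",
    "alarm_presession",
    "alarm_periodic",
    "alarm_low_battery",
    "detect_terminal_dropout",
    "run_qa",
    "BATTERY_THRESHOLD_PCT",
    "TERMINAL_DROPOUT_MIN_S",
    "PRESESSION_WINDOW_S",
    "PERIODIC_PERIOD_S",
]

#: Battery alert threshold (%): the alert exists so participants notice a
#: dying watch before the stream dies; the level itself is configurable.
BATTERY_THRESHOLD_PCT = 15.0

#: A terminal gap longer than this (s) is a dropout, not a transmission
#: hiccup: observed recoverable gaps ranged from 1 s up to 2 minutes, so
#: anything terminal beyond that ceiling never recovered.
TERMINAL_DROPOUT_MIN_S = 120.0

#: Look-back (s) of the pre-session presence check.
PRESESSION_WINDOW_S = 5.0

#: Tile length (s) of the periodic stream verification; tiles are aligned
#: to the window start.
PERIODIC_PERIOD_S = 300.0


class Severity(Enum):
    INFO = "info"
    WARNING = "warning"
    ERROR = "error"
    ALERT = "alert"  # reserved for the alarm rules


@dataclass(frozen=True)
class QAFinding:
    rule_id: str
    severity: Severity
    message: str
    session_id: str | None = None
    t_start: float | None = None
    t_end: float | None = None
    repaired: bool = False


@dataclass
class QAResult:
    findings: list[QAFinding]

    def summary(self) -> dict[str, dict[str, int]]:
        by_rule: dict[str, int] = {}
        by_severity: dict[str, int] = {}
        for f in self.findings:
            by_rule[f.rule_id] = by_rule.get(f.rule_id, 0) + 1
            by_severity[f.severity.value] = by_severity.get(f.severity.value, 0) + 1
        return {"by_rule": by_rule, "by_severity": by_severity}


_SEEK_KINDS = (ActionKind.FORWARD, ActionKind.REWIND,
               ActionKind.SKIP_INTRO, ActionKind.SKIP_CREDITS)


def check_coherence(session: Session) -> list[QAFinding]:
    """Action-sequence coherence of one session.

    Checks: a pause must belong to the same content as the play it follows
    (ERROR); two plays of the same content with nothing between them
    (WARNING); a pause with no prior play (WARNING); events stamped after
    the observed close (WARNING).
    """
    findings: list[QAFinding] = []
    sid = session.session_id
    last_play: ActionEvent | None = None
    seen_play = False
    play_unbroken = False  # a PLAY with no pause/seek since
    for e in session.events:
        if e.kind is ActionKind.PLAY:
            if (play_unbroken and last_play is not None
                    and last_play.content is not None and e.content is not None
                    and last_play.content == e.content):
                findings.append(QAFinding(
                    "coherence.double_play", Severity.WARNING,
                    "consecutive plays of the same content without an "
                    "intervening pause or seek",
                    session_id=sid, t_start=e.t,
                ))
            last_play = e
            seen_play = True
            play_unbroken = True
        elif e.kind is ActionKind.PAUSE:
            if not seen_play:
                findings.append(QAFinding(
                    "coherence.pause_without_play", Severity.WARNING,
                    "pause with no prior play", session_id=sid, t_start=e.t,
                ))
            elif (last_play is not None and last_play.content is not None
                    and e.content is not None and e.content != last_play.content):
                findings.append(QAFinding(
                    "coherence.pause_content_mismatch", Severity.ERROR,
                    f"pause on {e.content.title_id}/{e.content.episode_id or '-'} "
                    f"after play of {last_play.content.title_id}"
                    f"/{last_play.content.episode_id or '-'}",
                    session_id=sid, t_start=e.t,
                ))
            play_unbroken = False
        elif e.kind in _SEEK_KINDS:
            play_unbroken = False
        if session.observed_end_t is not None and e.t > session.observed_end_t:
            findings.append(QAFinding(
                "coherence.event_after_end", Severity.WARNING,
                f"{e.kind.value} after the observed session end",
                session_id=sid, t_start=e.t,
            ))
    return findings


def alarm_presession(
    samples: Sequence[PhysioSample],
    session_start_t: float,
    session_id: str | None = None,
    window_s: float = PRESESSION_WINDOW_S,
) -> QAFinding | None:
    """ALERT when no physiological data arrived in the five seconds before
    the session started (half-open window [start − window_s, start))."""
    lo = session_start_t - window_s
    for s in samples:
        if lo <= s.t < session_start_t:
            return None
    return QAFinding(
        "alarm.presession_no_data", Severity.ALERT,
        f"no physiological data in the {window_s:.0f} s before session start",
        session_id=session_id, t_start=lo, t_end=session_start_t,
    )


def alarm_periodic(
    samples: Sequence[PhysioSample],
    window: tuple[float, float],
    session_id: str | None = None,
    period_s: float = PERIODIC_PERIOD_S,
) -> list[QAFinding]:
    """ALERT for every ``period_s`` tile of the window with zero samples.

    Tiles are consecutive from the window start; a final partial tile is
    checked like any other.
    """
    s, e = window
    if e <= s:
        return []
    ts = sorted(x.t for x in samples)
    findings: list[QAFinding] = []
    tile_start = s
    while tile_start < e:
        tile_end = min(tile_start + period_s, e)
        i = bisect_left(ts, tile_start)
        if i >= len(ts) or ts[i] >= tile_end:
            findings.append(QAFinding(
                "alarm.periodic_silence", Severity.ALERT,
                f"no data in verification tile [{tile_start:.0f}, {tile_end:.0f})",
                session_id=session_id, t_start=tile_start, t_end=tile_end,
            ))
        tile_start += period_s
    return findings


def alarm_low_battery(
    samples: Sequence[PhysioSample],
    session_id: str | None = None,
    threshold_pct: float = BATTERY_THRESHOLD_PCT,
) -> list[QAFinding]:
    """One ALERT per device at its first sample below the battery threshold;
    an INFO when the stream carries no battery column at all."""
    findings: list[QAFinding] = []
    alerted: set[str] = set()
    any_battery = False
    for s in samples:
        if s.battery_pct is None:
            continue
        any_battery = True
        if s.device_id not in alerted and s.battery_pct < threshold_pct:
            alerted.add(s.device_id)
            findings.append(QAFinding(
                "alarm.low_battery", Severity.ALERT,
                f"device {s.device_id} battery at {s.battery_pct:.0f}% "
                f"(threshold {threshold_pct:.0f}%)",
                session_id=session_id, t_start=s.t,
            ))
    if not any_battery and len(list(samples)) > 0:
        findings.append(QAFinding(
            "qa.battery_unavailable", Severity.INFO,
            "battery level unavailable in this stream", session_id=session_id,
        ))
    return findings


def detect_terminal_dropout(
    report: CoverageReport, min_duration_s: float = TERMINAL_DROPOUT_MIN_S
) -> QAFinding | None:
    """ERROR when the stream died mid-session and never recovered.

    Fires on a terminal gap longer than ``min_duration_s`` — beyond the
    ceiling of gaps that were ever observed to recover.
    """
    for g in report.gaps:
        if g.terminal and g.duration_s > min_duration_s:
            return QAFinding(
                "dropout.terminal", Severity.ERROR,
                f"stream stopped {g.duration_s:.0f} s before the session end "
                "and never recovered",
                session_id=report.session_id, t_start=g.start_t, t_end=g.end_t,
            )
    return None


def run_qa(
    sessions: Sequence[Session],
    timelines: Mapping[str, Timeline],
    reports: Mapping[str, CoverageReport],
    samples_by_participant: Mapping[str, Sequence[PhysioSample]],
    *,
    normalization_notes: Sequence[NormalizationNote] = (),
    repair_flags: Mapping[str, Sequence[RepairFlag]] = {},
    stray_events: Sequence[ActionEvent] = (),
    battery_threshold_pct: float = BATTERY_THRESHOLD_PCT,
    terminal_dropout_min_s: float = TERMINAL_DROPOUT_MIN_S,
    presession_window_s: float = PRESESSION_WINDOW_S,
    period_s: float = PERIODIC_PERIOD_S,
) -> QAResult:
    """Run every rule over a computed study bundle.

    The output is the deterministic concatenation of all rule findings,
    ordered by (session, time, rule id); study-level findings (stream
    normalization, stray events) sort first.
    """
    findings: list[QAFinding] = []
    for n in normalization_notes:
        sev = Severity.INFO
        findings.append(QAFinding(
            f"normalize.{n.rule}", sev, n.message,
            session_id=None, t_start=n.t, repaired=True,
        ))
    for e in stray_events:
        findings.append(QAFinding(
            "sessionize.stray_event", Severity.WARNING,
            f"{e.kind.value} outside any session ({e.participant_id})",
            session_id=None, t_start=e.t,
        ))
    for s in sessions:
        sid = s.session_id
        for flag in s.flags:
            sev = Severity.WARNING if flag != "watch_start_inferred_from_samples" else Severity.INFO
            findings.append(QAFinding(
                f"sessionize.{flag}", sev, flag.replace("_", " "), session_id=sid,
                t_start=s.start_t,
            ))
        for rf in repair_flags.get(sid, ()):  # stamp repairs from playback
            sev = Severity.WARNING
            findings.append(QAFinding(
                f"repair.{rf.rule}", sev, rf.detail, session_id=sid,
                t_start=rf.t, repaired=rf.repaired,
            ))
        tl = timelines.get(sid)
        if tl is not None:
            for a in tl.anomalies:
                findings.append(QAFinding(
                    f"playback.{a.kind}", Severity.WARNING, a.message,
                    session_id=sid, t_start=a.t,
                ))
        findings.extend(check_coherence(s))
        part_samples = list(samples_by_participant.get(s.participant_id, ()))
        pre = alarm_presession(part_samples, s.start_t, session_id=sid,
                               window_s=presession_window_s)
        if pre is not None:
            findings.append(pre)
        rep = reports.get(sid)
        if rep is not None:
            findings.extend(alarm_periodic(
                part_samples, rep.window_dc, session_id=sid, period_s=period_s))
            td = detect_terminal_dropout(rep, min_duration_s=terminal_dropout_min_s)
            if td is not None:
                findings.append(td)
            in_window = [x for x in part_samples
                         if rep.window_dc[0] <= x.t < rep.window_dc[1]]
            findings.extend(alarm_low_battery(
                in_window, session_id=sid, threshold_pct=battery_threshold_pct))
    findings.sort(key=lambda f: (f.session_id or "", f.t_start or 0.0, f.rule_id))
    return QAResult(findings=findings)
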