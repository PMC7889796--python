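"""Analysis surfaces: summary tables, histograms and per-session views.

Every aggregate here is a pure function of the pipeline result, so the same
tables can be recomputed from the CSV exports alone.  Percentages are
rendered to two decimals in the exported tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .coverage import CoverageReport
from .events_io import ActionEvent, PhysioSample, format_timestamp
from .pipeline import StudyResult
from .playback import PlayState, Timeline
from .sessionize import Session, SessionClass

__all__ = [
    "StudySummary",
    "session_summary_table",
    "action_histogram",
    "content_per_session",
    "sessions_table",
    "coverage_table",
    "timelines_table",
    "findings_table",
    "render_session_view",
    "study_tables",
]


@dataclass
class StudySummary:
    """Per-class session counts and mean coverage metrics."""

    rows: pd.DataFrame
    per_participant: dict[str, int]
    total_actions: int


def _mean2(values: list[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    return round(sum(vals) / len(vals), 2)


def session_summary_table(
    sessions: Sequence[Session], reports: Mapping[str, CoverageReport]
) -> StudySummary:
    """The study-level coverage table: Category / # / DC / DT / CC / CT.

    Categories are Valid, Valid with HR, Semi-valid, Semi-valid with HR and
    Empty, where "with HR" restricts to sessions with at least one heart
    rate sample inside the coverage window.  Means are taken only over
    sessions where the metric is defined, rendered to 2 decimals.
    """
    groups: dict[str, list[Session]] = {
        "Valid Sessions": [], "Valid Sessions with HR": [],
        "Semi Valid Sessions": [], "Semi Valid Sessions with HR": [],
        "Empty Sessions": [],
    }
    for s in sessions:
        rep = reports.get(s.session_id)
        if s.classification is SessionClass.VALID:
            groups["Valid Sessions"].append(s)
            if rep is not None and rep.has_hr:
                groups["Valid Sessions with HR"].append(s)
        elif s.classification is SessionClass.SEMI_VALID:
            groups["Semi Valid Sessions"].append(s)
            if rep is not None and rep.has_hr:
                groups["Semi Valid Sessions with HR"].append(s)
        else:
            groups["Empty Sessions"].append(s)

    rows = []
    for name, members in groups.items():
        reps = [reports[s.session_id] for s in members if s.session_id in reports]
        rows.append({
            "Category": name,
            "#": len(members),
            "DC": _mean2([r.dc_pct for r in reps]),
            "DT": _mean2([r.dt_pct for r in reps]),
            "CC": _mean2([r.cc_pct for r in reps]),
            "CT": _mean2([r.ct_pct for r in reps]),
        })
    per_participant: dict[str, int] = {}
    total_actions = 0
    for s in sessions:
        per_participant[s.participant_id] = per_participant.get(s.participant_id, 0) + 1
        total_actions += s.n_events
    return StudySummary(
        rows=pd.DataFrame(rows, columns=["Category", "#", "DC", "DT", "CC", "CT"]),
        per_participant=per_participant,
        total_actions=total_actions,
    )


def action_histogram(events: Sequence[ActionEvent], bin: str = "hour") -> pd.DataFrame:
    """Counts of actions per (time bin, kind); totals equal the event count."""
    if bin not in ("hour", "day"):
        raise ValueError(f"unknown bin: {bin!r}")
    width = 3600 if bin == "hour" else 86400
    if not events:
        return pd.DataFrame(columns=["bin", "kind", "count"])
    recs = [
        {"bin": format_timestamp(math.floor(e.t / width) * width), "kind": e.kind.value}
        for e in events
    ]
    df = pd.DataFrame(recs).groupby(["bin", "kind"]).size().reset_index(name="count")
    return df.sort_values(["bin", "kind"]).reset_index(drop=True)


def content_per_session(
    sessions: Sequence[Session], timelines: Mapping[str, Timeline]
) -> pd.DataFrame:
    """Per session and content item: media span and watched wall seconds.

    Watched seconds sum to the session's total playing time (conservation).
    """
    rows = []
    for s in sessions:
        tl = timelines.get(s.session_id)
        if tl is None:
            continue
        agg: dict[tuple[str, str | None], dict] = {}
        for seg in tl.segments:
            if seg.state is not PlayState.PLAYING or seg.content is None:
                continue
            key = (seg.content.title_id, seg.content.episode_id)
            entry = agg.setdefault(key, {"first": None, "last": None, "wall": 0.0})
            entry["wall"] += seg.duration_s
            if seg.media_start is not None:
                m0, m1 = seg.media_start, seg.media_end
                entry["first"] = m0 if entry["first"] is None else min(entry["first"], m0)
                entry["last"] = m1 if entry["last"] is None else max(entry["last"], m1)
        for (title, episode), entry in agg.items():
            rows.append({
                "session_id": s.session_id, "title_id": title, "episode_id": episode,
                "first_media_s": entry["first"], "last_media_s": entry["last"],
                "watched_wall_s": round(entry["wall"], 3),
            })
    return pd.DataFrame(rows, columns=["session_id", "title_id", "episode_id",
                                       "first_media_s", "last_media_s", "watched_wall_s"])


# ---------------------------------------------------------------------------
# flat table exports


def sessions_table(sessions: Sequence[Session]) -> pd.DataFrame:
    return pd.DataFrame([{
        "session_id": s.session_id,
        "participant_id": s.participant_id,
        "start": format_timestamp(s.start_t),
        "observed_end": None if s.observed_end_t is None else format_timestamp(s.observed_end_t),
        "effective_end": None if s.effective_end_t is None else format_timestamp(s.effective_end_t),
        "class": s.classification.value if s.classification else None,
        "n_events": s.n_events,
        "has_content": s.has_content,
        "watch_start": None if s.watch_start_t is None else format_timestamp(s.watch_start_t),
        "flags": ";".join(s.flags),
    } for s in sessions])


def coverage_table(reports: Mapping[str, CoverageReport]) -> pd.DataFrame:
    rows = []
    for sid in sorted(reports):
        r = reports[sid]
        rows.append({
            "session_id": sid,
            "expected_dc": r.expected_dc, "observed_dc": r.observed_dc,
            "expected_dt": r.expected_dt, "observed_dt": r.observed_dt,
            "expected_cc": r.expected_cc, "observed_cc": r.observed_cc,
            "expected_ct": r.expected_ct, "observed_ct": r.observed_ct,
            "DC": None if r.dc_pct is None else round(r.dc_pct, 2),
            "DT": None if r.dt_pct is None else round(r.dt_pct, 2),
            "CC": None if r.cc_pct is None else round(r.cc_pct, 2),
            "CT": None if r.ct_pct is None else round(r.ct_pct, 2),
            "n_gaps": len(r.gaps),
            "has_hr": r.has_hr,
        })
    return pd.DataFrame(rows)


def timelines_table(timelines: Mapping[str, Timeline]) -> pd.DataFrame:
    rows = []
    for sid in sorted(timelines):
        for seg in timelines[sid].segments:
            rows.append({
                "session_id": sid,
                "title_id": seg.content.title_id if seg.content else None,
                "episode_id": seg.content.episode_id if seg.content else None,
                "state": seg.state.value,
                "wall_start": format_timestamp(seg.t0),
                "wall_end": format_timestamp(seg.t1),
                "media_start": seg.media_start,
                "media_end": seg.media_end,
            })
    return pd.DataFrame(rows, columns=["session_id", "title_id", "episode_id", "state",
                                       "wall_start", "wall_end", "media_start", "media_end"])


def findings_table(result: StudyResult) -> pd.DataFrame:
    return pd.DataFrame([{
        "rule_id": f.rule_id,
        "severity": f.severity.value,
        "session_id": f.session_id,
        "t_start": None if f.t_start is None else format_timestamp(f.t_start),
        "t_end": None if f.t_end is None else format_timestamp(f.t_end),
        "message": f.message,
        "repaired": f.repaired,
    } for f in result.qa.findings],
        columns=["rule_id", "severity", "session_id", "t_start", "t_end",
                 "message", "repaired"])


def study_tables(result: StudyResult, events: Sequence[ActionEvent] = ()) -> dict[str, pd.DataFrame]:
    """All exportable tables of a study result, keyed by table name."""
    summary = session_summary_table(result.sessions, result.reports)
    tables = {
        "sessions": sessions_table(result.sessions),
        "coverage": coverage_table(result.reports),
        "timelines": timelines_table(result.timelines),
        "findings": findings_table(result),
        "summary": summary.rows,
        "content_per_session": content_per_session(result.sessions, result.timelines),
    }
    if events:
        tables["action_histogram"] = action_histogram(events)
    return tables


# ---------------------------------------------------------------------------
# per-session view


def build_session_figure(
    session: Session,
    timeline: Timeline,
    annotated: Sequence[tuple[PhysioSample, object, object]],
    report: CoverageReport,
):
    """Matplotlib figure for one session: the heart-rate trace over wall
    time with playing bands, gap shading and action markers.

    Artists carry ``gid`` tags (``playing-band``, ``gap``, ``action``,
    ``hr-trace``) so the figure's data layers can be asserted without
    pixel comparison.  The caller owns (and must close) the figure.
    """
    fig, ax = plt.subplots(figsize=(10, 4))
    t0 = session.start_t
    for seg in timeline.segments:
        if seg.state is PlayState.PLAYING:
            patch = ax.axvspan(seg.t0 - t0, seg.t1 - t0, color="#c8e6c9", alpha=0.6)
            patch.set_gid("playing-band")
    for gap in report.gaps:
        patch = ax.axvspan(gap.start_t - t0, gap.end_t - t0, color="#ffcdd2", alpha=0.6)
        patch.set_gid("gap")
    ts = [s.t - t0 for s, _, _ in annotated if s.hr_bpm is not None]
    hrs = [s.hr_bpm for s, _, _ in annotated if s.hr_bpm is not None]
    if ts:
        (line,) = ax.plot(ts, hrs, lw=0.7, color="#1565c0")
        line.set_gid("hr-trace")
    for e in session.events:
        marker = ax.axvline(e.t - t0, color="#424242", lw=0.5, ls=":")
        marker.set_gid("action")
    ax.set_xlabel("seconds since session start")
    ax.set_ylabel("heart rate (bpm)")
    cls = session.classification.value if session.classification else "?"
    dc = f"{report.dc_pct:.2f}%" if report.dc_pct is not None else "n/a"
    ax.set_title(f"{session.session_id} [{cls}] DC {dc}")
    return fig


def render_session_view(
    session: Session,
    timeline: Timeline,
    annotated: Sequence[tuple[PhysioSample, object, object]],
    report: CoverageReport,
    out_path: str | Path,
) -> Path:
    """Render :func:`build_session_figure` to an image file."""
    fig = build_session_figure(session, timeline, annotated, report)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
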