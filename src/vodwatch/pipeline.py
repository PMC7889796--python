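"""End-to-end orchestration: raw streams in, analysis surfaces out.

``run_study`` chains the modules in their natural order — normalize the
event stream, segment and classify sessions, repair content stamps, rebuild
playback timelines, compute coverage, run QA — and collects every
intermediate product so reports and exports are pure functions of the
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import PipelineConfig
from .coverage import CoverageReport, compute_coverage
from .events_io import (
    ActionEvent,
    NormalizationNote,
    PhysioSample,
    StreamMarker,
    normalize_events,
)
from .playback import RepairFlag, Timeline, build_timeline, repair_content_stamps
from .qa import QAResult, run_qa
from .sessionize import Session, build_sessions

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    sessions: list[Session]
    timelines: dict[str, Timeline]
    reports: dict[str, CoverageReport]
    qa: QAResult
    stray_events: list[ActionEvent]
    normalization_notes: list[NormalizationNote]
    repair_flags: dict[str, list[RepairFlag]] = field(default_factory=dict)

    def session(self, session_id: str) -> Session:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(session_id)


def run_study(
    events: Sequence[ActionEvent],
    samples: Sequence[PhysioSample] = (),
    markers: Sequence[StreamMarker] = (),
    config: PipelineConfig | None = None,
) -> StudyResult:
    """Run the full analysis over one study's raw streams."""
    cfg = config or PipelineConfig()
    ordered, notes = normalize_events(events)

    samples_by_pid: dict[str, list[PhysioSample]] = {}
    for s in samples:
        samples_by_pid.setdefault(s.participant_id, []).append(s)

    seg = build_sessions(ordered, markers=markers, samples=samples,
                         lookback_s=cfg.watch_fallback_lookback_s)
    sessions = seg.sessions

    timelines: dict[str, Timeline] = {}
    reports: dict[str, CoverageReport] = {}
    repair_flags: dict[str, list[RepairFlag]] = {}
    for i, sess in enumerate(sessions):
        repaired, flags = repair_content_stamps(sess, repair_window_s=cfg.repair_window_s)
        if flags:
            repair_flags[sess.session_id] = flags
        sessions[i] = repaired
        tl = build_timeline(repaired, drift_tol_s=cfg.drift_tol_s)
        timelines[repaired.session_id] = tl
        part_samples = samples_by_pid.get(repaired.participant_id, [])
        reports[repaired.session_id] = compute_coverage(
            repaired, tl, part_samples, gap_min_s=cfg.gap_min_s)

    qa_result = run_qa(
        sessions, timelines, reports, samples_by_pid,
        normalization_notes=notes,
        repair_flags=repair_flags,
        stray_events=seg.stray_events,
        battery_threshold_pct=cfg.battery_threshold_pct,
        terminal_dropout_min_s=cfg.terminal_dropout_min_s,
        presession_window_s=cfg.presession_window_s,
        period_s=cfg.period_s,
    )
    return StudyResult(
        sessions=sessions, timelines=timelines, reports=reports, qa=qa_result,
        stray_events=seg.stray_events, normalization_notes=notes,
        repair_flags=repair_flags,
    )
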