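"""Synthetic viewing studies: action logs + wearable streams + ground truth.

The generator emulates the structure of at-home evening VOD studies: each
participant-night produces one session that is either *empty* (open the
site, browse, close), *valid* (play one or more episodes, pause and seek,
close the tab) or *semi-valid* (same, but the tab close is never recorded).
Episodes default to the ~42 m 23 s mean length of real binge-watched
content, watched either three-in-a-row (binge arm) or one per night
(control arm).  The wearable emits one sample per second from the watch
"Start" press (shortly before the session) until shortly after it ends.

Faults are injected only on request, each with an exact inventory so every
downstream detector can be scored with known ground truth:

* per-second i.i.d. sample loss, recoverable 1–120 s transmission gaps and
  terminal dropout (the stream dies and never recovers);
* empty-content stamps on episode-switch events;
* stale stamps (previous episode's frame of reference on the new episode);
* same-timestamp out-of-order server writes.

Heart rate is an AR(1) fluctuation around a resting baseline — coverage
accounting only needs sample *presence*, so no cardiac realism is claimed.
Everything is driven by one mandatory seed; a fixed config yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from .events_io import (
    ActionEvent,
    ActionKind,
    ContentRef,
    MarkerKind,
    PhysioSample,
    StreamMarker,
    write_action_log,
    write_marker_csv,
    write_physio_csv,
)
from .sessionize import make_session_id

__all__ = [
    "DropoutModel",
    "HRModel",
    "FaultToggles",
    "SimConfig",
    "SessionTruth",
    "GroundTruth",
    "SimStudy",
    "simulate_study",
    "inject_dropout",
    "inject_log_faults",
]

#: First study night: an arbitrary evening-at-home anchor (22:00 UTC).
_BASE_EPOCH = datetime(2019, 6, 1, 22, 0, tzinfo=timezone.utc).timestamp()


def _q(t: float) -> float:
    """Quantize to milliseconds: the server's write resolution."""
    return round(t, 3)


@dataclass
class DropoutModel:
    """Sample-loss model for the wearable stream."""

    miss_prob: float = 0.0  # i.i.d. per-second loss
    recoverable_gap_rate_per_hour: float = 0.0
    gap_duration_range_s: tuple[int, int] = (1, 120)
    terminal_dropout_prob: float = 0.0

    def validate(self) -> None:
        for p in (self.miss_prob, self.terminal_dropout_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("dropout probabilities must be in [0, 1]")
        lo, hi = self.gap_duration_range_s
        if not (1 <= lo <= hi):
            raise ValueError("gap_duration_range_s must satisfy 1 <= lo <= hi")
        if self.recoverable_gap_rate_per_hour < 0:
            raise ValueError("gap rate must be non-negative")


@dataclass
class HRModel:
    """AR(1) heart-rate fluctuation around a resting baseline."""

    baseline_bpm: float = 72.0
    sd_bpm: float = 6.0
    ar1_coef: float = 0.97


@dataclass
class FaultToggles:
    """Event-log fault families (all off by default)."""

    empty_content: bool = False
    stale_stamp: bool = False
    same_time_disorder: bool = False

    @property
    def any(self) -> bool:
        return self.empty_content or self.stale_stamp or self.same_time_disorder


@dataclass
class SimConfig:
    """Study design and behaviour parameters.

    Defaults describe the binge arm of an evening at-home study: three
    ~2543 s episodes in a row per night, a couple of pauses and occasional
    seeks per hour, watch started about half a minute before opening the
    site.  The seed is mandatory — there is no unseeded mode.
    """

    seed: int
    n_participants: int = 10
    nights_per_participant: int = 3
    episodes_per_session: int = 3
    episode_runtime_mean_s: float = 2543.0
    episode_runtime_sd_s: float = 300.0
    pause_rate_per_hour: float = 2.0
    pause_duration_mean_s: float = 60.0
    seek_rate_per_hour: float = 1.5
    skip_credits_prob: float = 0.5
    skip_intro_prob: float = 0.4
    semi_valid_prob: float = 0.2
    empty_session_prob: float = 0.35
    watch_start_offset_mean_s: float = 30.0
    watch_start_offset_sd_s: float = 10.0
    watch_missing_prob: float = 0.0
    dropout: DropoutModel = field(default_factory=DropoutModel)
    hr: HRModel = field(default_factory=HRModel)
    faults: FaultToggles = field(default_factory=FaultToggles)

    def validate(self) -> None:
        for name in ("skip_credits_prob", "skip_intro_prob", "semi_valid_prob",
                     "empty_session_prob", "watch_missing_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.episode_runtime_mean_s <= 0:
            raise ValueError("episode runtime must be positive")
        if self.n_participants < 1 or self.nights_per_participant < 1:
            raise ValueError("need at least one participant-night")
        if self.episodes_per_session < 1:
            raise ValueError("need at least one episode per session")
        self.dropout.validate()


@dataclass
class SessionTruth:
    """Everything the generator knows about one emitted session."""

    session_id: str
    participant_id: str
    classification: str  # valid | semi_valid | empty
    start_t: float
    observed_end_t: float | None
    effective_end_t: float
    watch_start_t: float | None
    playing_intervals: list[tuple[float, float]]
    n_episodes: int
    deleted_buckets: list[int] = field(default_factory=list)
    recoverable_gaps: list[tuple[int, int]] = field(default_factory=list)
    terminal_cut_bucket: int | None = None
    fault_events: dict[str, list[float]] = field(default_factory=dict)
    dc_pct: float | None = None
    dt_pct: float | None = None
    cc_pct: float | None = None
    ct_pct: float | None = None


@dataclass
class GroundTruth:
    sessions: dict[str, SessionTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {sid: dataclasses.asdict(st) for sid, st in self.sessions.items()}
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SimStudy:
    """A complete simulated study, ready to be written or piped onward."""

    events: list[ActionEvent]
    samples: list[PhysioSample]
    markers: list[StreamMarker]
    truth: GroundTruth
    config: SimConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "events": write_action_log(self.events, out / "events.jsonl", "jsonl"),
            "physio": write_physio_csv(self.samples, out / "physio.csv"),
            "markers": write_marker_csv(self.markers, out / "markers.csv"),
        }
        gt = out / "ground_truth.json"
        gt.write_text(self.truth.to_json() + "\n", encoding="utf-8")
        paths["ground_truth"] = gt
        return paths


# ---------------------------------------------------------------------------
# single-session generation


@dataclass
class _SessionDraft:
    events: list[ActionEvent]
    truth: SessionTruth
    samples: list[PhysioSample]
    markers: list[StreamMarker]


def _gen_content_session(
    pid: str, t0: float, cfg: SimConfig, rng: np.random.Generator,
    semi_valid: bool, title_id: str,
) -> tuple[list[ActionEvent], SessionTruth]:
    events: list[ActionEvent] = [
        ActionEvent(pid, _q(t0), ActionKind.SESSION_START)
    ]
    if rng.random() < 0.6:
        events.append(ActionEvent(pid, _q(t0 + rng.uniform(5, 15)), ActionKind.SEARCH))
    t = t0 + rng.uniform(20, 90)
    playing: list[tuple[float, float]] = []
    play_open: float | None = None
    combined_rate = (cfg.pause_rate_per_hour + cfg.seek_rate_per_hour) / 3600.0
    pause_share = (cfg.pause_rate_per_hour / (cfg.pause_rate_per_hour + cfg.seek_rate_per_hour)
                   if cfg.pause_rate_per_hour + cfg.seek_rate_per_hour > 0 else 0.0)
    media = 0.0
    content: ContentRef | None = None
    for ep in range(cfg.episodes_per_session):
        runtime = max(300.0, rng.normal(cfg.episode_runtime_mean_s, cfg.episode_runtime_sd_s))
        runtime = round(runtime, 1)
        content = ContentRef(title_id=title_id, episode_id=f"s01e{ep + 1:02d}",
                             runtime_s=runtime)
        t = _q(t)
        events.append(ActionEvent(pid, t, ActionKind.PLAY, content, media_pos_s=0.0))
        if play_open is None:
            play_open = t
        media = 0.0
        end_media = runtime
        skip_credits = rng.random() < cfg.skip_credits_prob
        if skip_credits:
            end_media = max(runtime * 0.5, runtime - 45.0)
        if rng.random() < cfg.skip_intro_prob:
            t = _q(t + 10.0)
            media = min(95.0, end_media * 0.5)
            events.append(ActionEvent(pid, t, ActionKind.SKIP_INTRO, content,
                                      media_pos_s=media))
        # playing-time Markov walk: exponential waits to the next interaction
        while True:
            dt = rng.exponential(1.0 / combined_rate) if combined_rate > 0 else math.inf
            if media + dt >= end_media:
                t = t + (end_media - media)
                media = end_media
                break
            t = _q(t + dt)
            media = round(media + dt, 3)
            if rng.random() < pause_share:
                events.append(ActionEvent(pid, t, ActionKind.PAUSE, content,
                                          media_pos_s=media))
                if play_open is not None:
                    playing.append((play_open, t))
                    play_open = None
                t = _q(t + min(900.0, 5.0 + rng.exponential(cfg.pause_duration_mean_s)))
                events.append(ActionEvent(pid, t, ActionKind.PLAY, content,
                                          media_pos_s=media))
                play_open = t
            else:
                lo = max(0.0, media - 300.0)
                hi = min(end_media * 0.98, media + 300.0)
                target = round(rng.uniform(lo, hi), 3)
                kind = ActionKind.FORWARD if target >= media else ActionKind.REWIND
                events.append(ActionEvent(pid, _q(t), ActionKind(kind), content,
                                          media_pos_s=target))
                media = target
        t = _q(t)
        if skip_credits:
            events.append(ActionEvent(pid, t, ActionKind.SKIP_CREDITS, content,
                                      media_pos_s=round(runtime, 3)))
            media = runtime
        if ep < cfg.episodes_per_session - 1:
            t = _q(t + rng.uniform(3, 8))  # auto-advance gap; still playing
    # the viewer stops playback at the end of the last episode
    t = _q(t)
    events.append(ActionEvent(pid, t, ActionKind.PAUSE, content, media_pos_s=round(media, 3)))
    if play_open is not None:
        playing.append((play_open, t))
        play_open = None
    last_pause_t = t
    observed_end: float | None = None
    if semi_valid:
        effective_end = last_pause_t
    else:
        observed_end = _q(t + rng.uniform(10, 120))
        events.append(ActionEvent(pid, observed_end, ActionKind.SESSION_END))
        effective_end = observed_end
    truth = SessionTruth(
        session_id=make_session_id(pid, _q(t0)),
        participant_id=pid,
        classification="semi_valid" if semi_valid else "valid",
        start_t=_q(t0), observed_end_t=observed_end, effective_end_t=effective_end,
        watch_start_t=None, playing_intervals=[(a, b) for a, b in playing],
        n_episodes=cfg.episodes_per_session,
    )
    return events, truth


def _gen_empty_session(
    pid: str, t0: float, cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[ActionEvent], SessionTruth]:
    events = [ActionEvent(pid, _q(t0), ActionKind.SESSION_START)]
    if rng.random() < 0.6:
        events.append(ActionEvent(pid, _q(t0 + rng.uniform(5, 25)), ActionKind.SEARCH))
    end = _q(t0 + rng.uniform(30, 240))
    events.append(ActionEvent(pid, end, ActionKind.SESSION_END))
    truth = SessionTruth(
        session_id=make_session_id(pid, _q(t0)), participant_id=pid,
        classification="empty", start_t=_q(t0), observed_end_t=end,
        effective_end_t=end, watch_start_t=None, playing_intervals=[],
        n_episodes=0,
    )
    return events, truth


def _gen_wearable(
    pid: str, device: str, truth: SessionTruth, cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[PhysioSample], list[StreamMarker]]:
    offset = max(5.0, rng.normal(cfg.watch_start_offset_mean_s, cfg.watch_start_offset_sd_s))
    watch_start = _q(truth.start_t - offset)
    stop = _q(truth.effective_end_t + rng.uniform(5, 30))
    truth.watch_start_t = watch_start
    markers = [
        StreamMarker(pid, device, watch_start, MarkerKind.WATCH_START),
        StreamMarker(pid, device, stop, MarkerKind.WATCH_STOP),
    ]
    k0, k1 = math.ceil(watch_start), math.ceil(stop)
    n = max(0, k1 - k0)
    h = cfg.hr
    innov_sd = h.sd_bpm * math.sqrt(max(0.0, 1.0 - h.ar1_coef ** 2))
    x0 = rng.normal(0.0, h.sd_bpm)
    innov = rng.normal(0.0, innov_sd, n)
    x = np.empty(n)
    prev = x0
    for i in range(n):  # AR(1) recursion
        prev = h.ar1_coef * prev + innov[i]
        x[i] = prev
    hr = np.round(h.baseline_bpm + x, 1)
    accel = np.round(rng.normal((0.0, 0.0, 9.81), 0.3, size=(n, 3)), 3)
    gyro = np.round(rng.normal(0.0, 0.05, size=(n, 3)), 3)
    battery0 = rng.uniform(60.0, 100.0)
    battery = np.round(np.maximum(0.0, battery0 - 4.0 * np.arange(n) / 3600.0), 1)
    samples = [
        PhysioSample(
            participant_id=pid, device_id=device, t=float(k0 + i),
            hr_bpm=float(hr[i]),
            accel_xyz=(float(accel[i, 0]), float(accel[i, 1]), float(accel[i, 2])),
            gyro_xyz=(float(gyro[i, 0]), float(gyro[i, 1]), float(gyro[i, 2])),
            battery_pct=float(battery[i]),
        )
        for i in range(n)
    ]
    return samples, markers


# ---------------------------------------------------------------------------
# fault injection


def inject_dropout(
    samples: Sequence[PhysioSample], model: DropoutModel, rng: np.random.Generator
) -> tuple[list[PhysioSample], dict]:
    """Delete samples per the dropout model; report exactly what was deleted.

    Three mechanisms, applied in order: i.i.d. per-second loss, contiguous
    recoverable gaps with durations in ``gap_duration_range_s``, and (with
    ``terminal_dropout_prob``) removal of everything after a uniform cut
    point in the second half of the stream.
    """
    model.validate()
    if not samples:
        return [], {"deleted_buckets": [], "recoverable_gaps": [], "terminal_cut_bucket": None}
    n = len(samples)
    keep = np.ones(n, dtype=bool)
    if model.miss_prob > 0:
        keep &= rng.random(n) >= model.miss_prob
    t_first = samples[0].t
    t_last = samples[-1].t
    duration_h = max(0.0, (t_last - t_first)) / 3600.0
    gaps: list[tuple[int, int]] = []
    if model.recoverable_gap_rate_per_hour > 0 and n > 2:
        n_gaps = rng.poisson(model.recoverable_gap_rate_per_hour * duration_h)
        lo, hi = model.gap_duration_range_s
        for _ in range(n_gaps):
            dur = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(1, n - dur)))
            keep[start:start + dur] = False
            gaps.append((int(math.floor(samples[start].t)),
                         int(math.floor(samples[min(n - 1, start + dur - 1)].t)) + 1))
    cut_bucket = None
    if model.terminal_dropout_prob > 0 and rng.random() < model.terminal_dropout_prob:
        cut = int(rng.integers(n // 2, n))
        keep[cut:] = False
        cut_bucket = int(math.floor(samples[cut].t))
    kept = [s for s, k in zip(samples, keep) if k]
    deleted = sorted({int(math.floor(s.t)) for s, k in zip(samples, keep) if not k})
    return kept, {
        "deleted_buckets": deleted,
        "recoverable_gaps": gaps,
        "terminal_cut_bucket": cut_bucket,
    }


def inject_log_faults(
    events: Sequence[ActionEvent], toggles: FaultToggles, rng: np.random.Generator
) -> tuple[list[ActionEvent], dict[str, list[float]]]:
    """Corrupt a clean event log the way the real collection pipeline did.

    * ``empty_content``: episode-switch PLAY events lose their content
      identity (the extension read the player too early).
    * ``stale_stamp``: episode-switch PLAY events keep the *previous*
      episode's identity with a position projected past its runtime.
    * ``same_time_disorder``: a session's SEARCH is stamped with the same
      timestamp as its SESSION_START and written before it — the wrong
      arrival order the server produced under same-second load.  Only
      timing-neutral kinds are disordered so behavioural ground truth is
      untouched.

    Returns the faulted stream (sorted as emitted) and an inventory mapping
    fault family to the affected event timestamps.
    """
    out = list(events)
    inventory: dict[str, list[float]] = {
        "empty_content": [], "stale_stamp": [], "same_time_disorder": [],
    }
    if toggles.empty_content or toggles.stale_stamp:
        prev_by_pid: dict[str, ContentRef] = {}
        for i, e in enumerate(out):
            if e.kind is ActionKind.SESSION_START:
                prev_by_pid.pop(e.participant_id, None)  # a switch is within-session
                continue
            if e.kind is not ActionKind.PLAY or e.content is None:
                continue
            prev_content = prev_by_pid.get(e.participant_id)
            is_switch = (
                prev_content is not None
                and e.content.episode_id != prev_content.episode_id
                and e.content.title_id == prev_content.title_id
                and e.media_pos_s == 0.0
            )
            if is_switch:
                if toggles.empty_content and toggles.stale_stamp:
                    use_empty = bool(rng.random() < 0.5)
                else:
                    use_empty = toggles.empty_content
                if use_empty:
                    out[i] = dataclasses.replace(e, content=None)
                    inventory["empty_content"].append(e.t)
                else:
                    stale_pos = (prev_content.runtime_s or 0.0) + 1.0
                    out[i] = dataclasses.replace(
                        e, content=prev_content, media_pos_s=round(stale_pos, 3))
                    inventory["stale_stamp"].append(e.t)
            prev_by_pid[e.participant_id] = e.content
    if toggles.same_time_disorder:
        # pair each session's start with its search, collapse timestamps,
        # and emit them in reversed (wrong) order
        i = 0
        while i < len(out) - 1:
            a, b = out[i], out[i + 1]
            if (a.kind is ActionKind.SESSION_START and b.kind is ActionKind.SEARCH
                    and a.participant_id == b.participant_id):
                b2 = dataclasses.replace(b, t=a.t)
                out[i], out[i + 1] = b2, a
                inventory["same_time_disorder"].append(a.t)
                i += 2
                continue
            i += 1
    return out, inventory


# ---------------------------------------------------------------------------
# study assembly


def _per_second_truth(truth: SessionTruth, kept_buckets: set[int]) -> None:
    """Fill the four coverage fractions by brute-force second enumeration.

    Uses the same bucket membership rule as the analytics (k in [s, e) on
    the integer grid) but derives everything from the generator's own
    records, independently of the pipeline implementation.
    """
    kept_arr = np.array(sorted(kept_buckets), dtype=np.int64)

    def frac(window: tuple[float, float] | None, restrict: bool) -> float | None:
        if window is None:
            return None
        s, e = window
        ks = np.arange(math.ceil(s), math.ceil(e), dtype=np.int64)
        if restrict:
            in_play = np.zeros(ks.shape, dtype=bool)
            for a, b in truth.playing_intervals:
                in_play |= (ks >= a) & (ks < b)
            ks = ks[in_play]
        exp = int(ks.size)
        if exp == 0:
            return None
        obs = int(np.isin(ks, kept_arr, assume_unique=False).sum())
        return 100.0 * obs / exp

    win_dc = (truth.start_t, truth.effective_end_t)
    win_dt = ((truth.watch_start_t, truth.effective_end_t)
              if truth.watch_start_t is not None else None)
    truth.dc_pct = frac(win_dc, restrict=False)
    truth.dt_pct = frac(win_dt, restrict=False)
    if truth.playing_intervals:
        truth.cc_pct = frac(win_dc, restrict=True)
        truth.ct_pct = frac(win_dt, restrict=True)


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate a full study under the configured conditions.

    Deterministic under a fixed config (including the seed): participants
    and nights are generated in a fixed order from one generator stream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    all_events: list[ActionEvent] = []
    all_samples: list[PhysioSample] = []
    all_markers: list[StreamMarker] = []
    truth = GroundTruth()

    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        device = f"W{p + 1:02d}"
        title = f"show-{p + 1:02d}"
        last_watch_start: float | None = None
        participant_kept: set[int] = set()
        for night in range(config.nights_per_participant):
            t0 = _q(_BASE_EPOCH + night * 86400.0 + p * 137.0 + rng.uniform(0, 1800))
            if rng.random() < config.empty_session_prob:
                events, st = _gen_empty_session(pid, t0, config, rng)
            else:
                semi = rng.random() < config.semi_valid_prob
                events, st = _gen_content_session(pid, t0, config, rng, semi, title)
            if rng.random() >= config.watch_missing_prob:
                samples, markers = _gen_wearable(pid, device, st, config, rng)
                samples, drop = inject_dropout(samples, config.dropout, rng)
                st.deleted_buckets = drop["deleted_buckets"]
                st.recoverable_gaps = drop["recoverable_gaps"]
                st.terminal_cut_bucket = drop["terminal_cut_bucket"]
                all_samples.extend(samples)
                all_markers.extend(markers)
                participant_kept |= {math.floor(s.t) for s in samples}
                last_watch_start = st.watch_start_t
            else:
                # no watch this night: the latest earlier Start press (if
                # any) is what the marker rule will resolve to downstream
                if last_watch_start is not None and last_watch_start <= st.effective_end_t:
                    st.watch_start_t = last_watch_start
            _per_second_truth(st, participant_kept)
            all_events.extend(events)
            truth.sessions[st.session_id] = st

    all_events.sort(key=lambda e: e.t)
    if config.faults.any:
        all_events, inventory = inject_log_faults(all_events, config.faults, rng)
        # attribute inventory entries to their sessions
        bounds = sorted(
            (st.start_t, st.effective_end_t if st.observed_end_t is None
             else st.observed_end_t, sid)
            for sid, st in truth.sessions.items()
        )
        for family, ts in inventory.items():
            for t in ts:
                for lo, hi, sid in bounds:
                    if lo <= t <= hi:
                        truth.sessions[sid].fault_events.setdefault(family, []).append(t)
                        break
    all_samples.sort(key=lambda s: (s.t, s.participant_id))
    all_markers.sort(key=lambda m: (m.t, m.participant_id))
    return SimStudy(events=all_events, samples=all_samples,
                    markers=all_markers, truth=truth, config=config)
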