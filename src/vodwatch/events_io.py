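"""Domain types and file I/O for viewer interaction logs and wearable streams.

The canonical on-disk formats are plain text:

* **Event log** — JSON Lines (one object per line) or RFC-4180 CSV with
  columns ``participant_id, t, kind, title_id, episode_id, runtime_s,
  media_pos_s, seq``.  Optional keys are omitted (JSONL) or left empty (CSV).
* **Physiological stream** — CSV with columns ``participant_id, device_id,
  t, hr_bpm, ax, ay, az, gx, gy, gz, battery_pct``; nominally one row per
  second per device.
* **Watch markers** — CSV with columns ``participant_id, device_id, t, kind``
  where kind is ``watch_start`` or ``watch_stop``.

Timestamps are UTC epoch seconds internally.  Readers accept either a numeric
epoch value or an ISO-8601 string in any time zone (naive strings are taken
as UTC); conversion happens only at this boundary.  JSONL writers emit the
numeric epoch form so that a write/read cycle is bit-exact; CSV writers emit
ISO-8601 UTC for human readability.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, fields, replace
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Union

import pandas as pd

__all__ = [
    "ActionKind",
    "ContentRef",
    "ActionEvent",
    "PhysioSample",
    "MarkerKind",
    "StreamMarker",
    "RecordError",
    "ActionLog",
    "NormalizationNote",
    "HR_BPM_BOUNDS",
    "KIND_PRECEDENCE",
    "parse_timestamp",
    "format_timestamp",
    "read_action_log",
    "write_action_log",
    "read_physio_stream",
    "write_physio_csv",
    "write_marker_csv",
    "normalize_events",
    "write_export",
]

PathLike = Union[str, Path]

#: Plausibility bounds for wrist-sensor heart rate, beats per minute.
#: Samples outside the open interval are kept but flagged; dropping is a
#: downstream QA decision, never the reader's.
HR_BPM_BOUNDS = (20.0, 250.0)


class ActionKind(str, Enum):
    """The eleven interface actions captured on the VOD player.

    ``SESSION_START``/``SESSION_END`` are the tab open/close boundary
    markers; the remainder are in-player interactions.
    """

    SESSION_START = "session_start"
    SESSION_END = "session_end"
    SEARCH = "search"
    PLAY = "play"
    PAUSE = "pause"
    FORWARD = "forward"
    REWIND = "rewind"
    SKIP_CREDITS = "skip_credits"
    SKIP_INTRO = "skip_intro"
    LOGIN = "login"
    LOGOUT = "logout"


#: Tie-break precedence for events sharing a timestamp.  Boundary markers
#: bracket content actions and PLAY precedes PAUSE, so a same-second
#: play/pause pair stays coherent after sorting.
KIND_PRECEDENCE: dict[ActionKind, int] = {
    ActionKind.SESSION_START: 0,
    ActionKind.LOGIN: 1,
    ActionKind.SEARCH: 2,
    ActionKind.PLAY: 3,
    ActionKind.SKIP_INTRO: 4,
    ActionKind.FORWARD: 5,
    ActionKind.REWIND: 6,
    ActionKind.SKIP_CREDITS: 7,
    ActionKind.PAUSE: 8,
    ActionKind.LOGOUT: 9,
    ActionKind.SESSION_END: 10,
}

_KIND_ALIASES = {
    "session_started": ActionKind.SESSION_START,
    "session_ended": ActionKind.SESSION_END,
    "open_tab": ActionKind.SESSION_START,
    "close_tab": ActionKind.SESSION_END,
}


def parse_action_kind(value: str) -> ActionKind:
    """Map a raw kind string to the closed 11-action vocabulary.

    Case, spaces and hyphens are normalized; a few boundary-marker spellings
    from other log dialects are accepted.  Anything else raises ValueError.
    """
    key = str(value).strip().lower().replace(" ", "_").replace("-", "_")
    try:
        return ActionKind(key)
    except ValueError:
        if key in _KIND_ALIASES:
            return _KIND_ALIASES[key]
        raise ValueError(f"unknown action kind: {value!r}") from None


@dataclass(frozen=True)
class ContentRef:
    """Identity of a content item: a title plus an optional episode.

    runtime_s is the episode length from metadata when known; it backs the
    stale-stamp check (a media position past the runtime cannot be real).
    """

    title_id: str
    episode_id: str | None = None
    runtime_s: float | None = None

    def __post_init__(self) -> None:
        if not self.title_id:
            raise ValueError("title_id must be non-empty")
        if self.runtime_s is not None and not self.runtime_s > 0:
            raise ValueError("runtime_s must be positive when present")


@dataclass(frozen=True)
class ActionEvent:
    """One timestamped viewer interaction.

    media_pos_s is the position on the content's own timeline at the instant
    of the event; for seeks and skips it is the post-jump position (the
    pre-jump position is recoverable from the playback state machine).
    source_seq is the arrival order at the server, used only to break
    same-timestamp ties.
    """

    participant_id: str
    t: float
    kind: ActionKind
    content: ContentRef | None = None
    media_pos_s: float | None = None
    source_seq: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValueError("event timestamp must be finite")
        if self.media_pos_s is not None and self.media_pos_s < 0:
            raise ValueError("media_pos_s must be non-negative")


@dataclass(frozen=True)
class PhysioSample:
    """One wearable record: heart rate, inertial axes, battery, at ~1 Hz.

    flags carries reader-side annotations (e.g. ``hr_out_of_range``); the
    sample itself is never dropped by the reader.
    """

    participant_id: str
    device_id: str
    t: float
    hr_bpm: float | None = None
    accel_xyz: tuple[float, float, float] | None = None
    gyro_xyz: tuple[float, float, float] | None = None
    battery_pct: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def has_signal(self) -> bool:
        """True when at least one physiological field is present."""
        return self.hr_bpm is not None or self.accel_xyz is not None or self.gyro_xyz is not None

    @property
    def hr_plausible(self) -> bool | None:
        if self.hr_bpm is None:
            return None
        lo, hi = HR_BPM_BOUNDS
        return lo < self.hr_bpm < hi


class MarkerKind(str, Enum):
    WATCH_START = "watch_start"
    WATCH_STOP = "watch_stop"


@dataclass(frozen=True)
class StreamMarker:
    """Start/stop press on the smartwatch app."""

    participant_id: str
    device_id: str
    t: float
    kind: MarkerKind


@dataclass(frozen=True)
class RecordError:
    """A malformed input record, collected instead of silently dropped."""

    line_no: int
    message: str
    raw: str


@dataclass
class ActionLog:
    """Result of reading an event log: parsed events plus per-record errors."""

    events: list[ActionEvent]
    errors: list[RecordError] = field(default_factory=list)

    def __iter__(self) -> Iterator[ActionEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class NormalizationNote:
    """Audit record of something normalize_events changed."""

    rule: str  # "duplicate_removed" | "same_time_reorder"
    participant_id: str
    t: float
    message: str


# ---------------------------------------------------------------------------
# timestamps


def parse_timestamp(value: object) -> float:
    """Parse an epoch number or ISO-8601 string to UTC epoch seconds."""
    if isinstance(value, bool):
        raise ValueError(f"not a timestamp: {value!r}")
    if isinstance(value, (int, float)):
        t = float(value)
        if not math.isfinite(t):
            raise ValueError("timestamp must be finite")
        return t
    s = str(value).strip()
    if not s:
        raise ValueError("empty timestamp")
    try:
        return float(s)
    except ValueError:
        pass
    if s.endswith(("Z", "z")):
        s = s[:-1] + "+00:00"
    dt = datetime.fromisoformat(s)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def format_timestamp(t: float) -> str:
    """UTC ISO-8601 rendering of an epoch-seconds timestamp."""
    return datetime.fromtimestamp(t, tz=timezone.utc).isoformat().replace("+00:00", "Z")


# ---------------------------------------------------------------------------
# event log reading / writing


def _opt_float(v: object) -> float | None:
    if v is None or v == "":
        return None
    return float(v)


def _opt_int(v: object) -> int | None:
    if v is None or v == "":
        return None
    return int(v)


def _record_to_event(rec: Mapping[str, object]) -> ActionEvent:
    pid = rec.get("participant_id") or rec.get("participant")
    if not pid:
        raise ValueError("missing participant_id")
    t_raw = rec.get("t", rec.get("timestamp"))
    if t_raw is None or t_raw == "":
        raise ValueError("missing timestamp")
    t = parse_timestamp(t_raw)
    kind_raw = rec.get("kind", rec.get("action"))
    if not kind_raw:
        raise ValueError("missing kind")
    kind = parse_action_kind(str(kind_raw))
    title_id = rec.get("title_id") or None
    content = None
    if title_id:
        content = ContentRef(
            title_id=str(title_id),
            episode_id=(str(rec["episode_id"]) if rec.get("episode_id") else None),
            runtime_s=_opt_float(rec.get("runtime_s")),
        )
    media_pos = _opt_float(rec.get("media_pos_s", rec.get("pos")))
    seq = _opt_int(rec.get("seq", rec.get("source_seq")))
    return ActionEvent(
        participant_id=str(pid), t=t, kind=kind, content=content,
        media_pos_s=media_pos, source_seq=seq,
    )


def _open_text(source: Union[PathLike, TextIO]) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False  # caller-owned stream
    return open(source, "r", encoding="utf-8", newline=""), True


def read_action_log(source: Union[PathLike, TextIO], dialect: str = "jsonl") -> ActionLog:
    """Read an interaction event log.

    Every well-formed record yields one :class:`ActionEvent`; malformed
    records (bad timestamp, unknown kind, missing fields) are collected as
    :class:`RecordError` entries in input order.

    Parameters
    ----------
    source
        File path or open text stream.
    dialect
        ``"jsonl"`` (one JSON object per line) or ``"csv"``.
    """
    if dialect not in ("jsonl", "csv"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    fh, owned = _open_text(source)
    events: list[ActionEvent] = []
    errors: list[RecordError] = []
    try:
        if dialect == "jsonl":
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                    if not isinstance(rec, dict):
                        raise ValueError("record is not a JSON object")
                    events.append(_record_to_event(rec))
                except (ValueError, TypeError) as exc:
                    errors.append(RecordError(i, str(exc), line))
        else:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):  # header is line 1
                try:
                    events.append(_record_to_event(row))
                except (ValueError, TypeError) as exc:
                    errors.append(RecordError(i, str(exc), ",".join(str(v) for v in row.values())))
    finally:
        if owned:
            fh.close()
    return ActionLog(events=events, errors=errors)


_EVENT_COLUMNS = ["participant_id", "t", "kind", "title_id", "episode_id",
                  "runtime_s", "media_pos_s", "seq"]


def _event_to_record(e: ActionEvent, iso: bool) -> dict[str, object]:
    rec: dict[str, object] = {
        "participant_id": e.participant_id,
        "t": format_timestamp(e.t) if iso else e.t,
        "kind": e.kind.value,
    }
    if e.content is not None:
        rec["title_id"] = e.content.title_id
        if e.content.episode_id is not None:
            rec["episode_id"] = e.content.episode_id
        if e.content.runtime_s is not None:
            rec["runtime_s"] = e.content.runtime_s
    if e.media_pos_s is not None:
        rec["media_pos_s"] = e.media_pos_s
    if e.source_seq is not None:
        rec["seq"] = e.source_seq
    return rec


def write_action_log(events: Iterable[ActionEvent], path: PathLike, dialect: str = "jsonl") -> Path:
    """Write events in the canonical log format (see module docstring)."""
    path = Path(path)
    if dialect == "jsonl":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for e in events:
                fh.write(json.dumps(_event_to_record(e, iso=False)) + "\n")
    elif dialect == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_EVENT_COLUMNS)
            writer.writeheader()
            for e in events:
                writer.writerow(_event_to_record(e, iso=True))
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# physiological stream reading / writing

_PHYSIO_MANDATORY = ("participant_id", "device_id", "t")
_PHYSIO_COLUMNS = ["participant_id", "device_id", "t", "hr_bpm",
                   "ax", "ay", "az", "gx", "gy", "gz", "battery_pct"]


def _row_to_sample(row: Mapping[str, object]) -> PhysioSample:
    t = parse_timestamp(row["t"])
    hr = _opt_float(row.get("hr_bpm"))
    accel = None
    if all(row.get(k) not in (None, "") for k in ("ax", "ay", "az")):
        accel = (float(row["ax"]), float(row["ay"]), float(row["az"]))
    gyro = None
    if all(row.get(k) not in (None, "") for k in ("gx", "gy", "gz")):
        gyro = (float(row["gx"]), float(row["gy"]), float(row["gz"]))
    battery = _opt_float(row.get("battery_pct"))
    flags: list[str] = []
    if hr is not None and not (HR_BPM_BOUNDS[0] < hr < HR_BPM_BOUNDS[1]):
        flags.append("hr_out_of_range")
    if hr is None and accel is None and gyro is None:
        flags.append("no_signal")
    return PhysioSample(
        participant_id=str(row["participant_id"]), device_id=str(row["device_id"]),
        t=t, hr_bpm=hr, accel_xyz=accel, gyro_xyz=gyro, battery_pct=battery,
        flags=tuple(flags),
    )


def read_physio_stream(
    source: PathLike, markers: PathLike | None = None
) -> tuple[list[PhysioSample], list[StreamMarker]]:
    """Read a wearable sample CSV plus an optional marker sidecar CSV.

    Samples come back in input order (timestamps need not be monotone — the
    server wrote them in arrival order).  Out-of-range heart rates are
    retained with an ``hr_out_of_range`` flag.  Missing mandatory columns
    are fatal.
    """
    with open(source, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = [c for c in _PHYSIO_MANDATORY if c not in cols]
        if missing:
            raise ValueError(f"physio stream missing mandatory columns: {missing}")
        samples = [_row_to_sample(row) for row in reader]
    marker_list: list[StreamMarker] = []
    if markers is not None:
        with open(markers, "r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                marker_list.append(StreamMarker(
                    participant_id=str(row["participant_id"]),
                    device_id=str(row["device_id"]),
                    t=parse_timestamp(row["t"]),
                    kind=MarkerKind(str(row["kind"]).strip().lower()),
                ))
    return samples, marker_list


def write_physio_csv(samples: Iterable[PhysioSample], path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PHYSIO_COLUMNS)
        for s in samples:
            ax, ay, az = s.accel_xyz if s.accel_xyz else ("", "", "")
            gx, gy, gz = s.gyro_xyz if s.gyro_xyz else ("", "", "")
            writer.writerow([
                s.participant_id, s.device_id, format_timestamp(s.t),
                "" if s.hr_bpm is None else s.hr_bpm,
                ax, ay, az, gx, gy, gz,
                "" if s.battery_pct is None else s.battery_pct,
            ])
    return path


def write_marker_csv(markers: Iterable[StreamMarker], path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "device_id", "t", "kind"])
        for m in markers:
            writer.writerow([m.participant_id, m.device_id, format_timestamp(m.t), m.kind.value])
    return path


# ---------------------------------------------------------------------------
# normalization


def normalize_events(
    events: Sequence[ActionEvent],
) -> tuple[list[ActionEvent], list[NormalizationNote]]:
    """Order and de-duplicate a raw event stream.

    The server occasionally wrote several same-second actions in the wrong
    arrival order, so sorting is by ``(t, kind precedence, source_seq)``
    with the precedence in :data:`KIND_PRECEDENCE`.  Exact duplicates (all
    fields equal) are removed.  Both repairs are reported as notes, never
    applied silently.  The operation is idempotent and insensitive to the
    input permutation.
    """
    def key(e: ActionEvent):
        seq = e.source_seq
        return (e.t, KIND_PRECEDENCE[e.kind], seq is None, 0 if seq is None else seq)

    ordered = sorted(events, key=key)
    notes: list[NormalizationNote] = []

    # Report same-timestamp groups whose input order disagreed with the
    # normalized order (the wrong-order server writes).
    input_rank = {id(e): i for i, e in enumerate(events)}
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j].t == ordered[i].t \
                and ordered[j].participant_id == ordered[i].participant_id:
            j += 1
        if j - i > 1:
            ranks = [input_rank[id(e)] for e in ordered[i:j]]
            if ranks != sorted(ranks):
                notes.append(NormalizationNote(
                    rule="same_time_reorder",
                    participant_id=ordered[i].participant_id,
                    t=ordered[i].t,
                    message=f"reordered {j - i} same-timestamp events",
                ))
        i = j

    deduped: list[ActionEvent] = []
    for e in ordered:
        if deduped and deduped[-1] == e:
            notes.append(NormalizationNote(
                rule="duplicate_removed", participant_id=e.participant_id, t=e.t,
                message=f"removed exact duplicate {e.kind.value} record",
            ))
            continue
        deduped.append(e)
    return deduped, notes


# ---------------------------------------------------------------------------
# tabular export


def write_export(
    tables: Mapping[str, pd.DataFrame], out_dir: PathLike, format: str = "csv"
) -> dict[str, Path]:
    """Write named tables for downstream statistical packages.

    CSV output is RFC-4180 (pandas quoting), UTF-8; JSON output is
    records-oriented.  Returns the written paths keyed by table name.
    """
    if format not in ("csv", "json"):
        raise ValueError(f"unknown export format: {format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        if format == "csv":
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        else:
            path = out_dir / f"{name}.json"
            df.to_json(path, orient="records", indent=2)
        written[name] = path
    return written
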