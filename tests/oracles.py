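"""Independent brute-force oracles.

These deliberately avoid the interval arithmetic of the package: the
playback oracle re-derives the media position at a single instant by
replaying the raw event list from scratch, and the coverage oracle counts
individual integer seconds.  They are slow and simple on purpose.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

from vodwatch.events_io import ActionEvent, ActionKind

_SEEKS = (ActionKind.FORWARD, ActionKind.REWIND,
          ActionKind.SKIP_INTRO, ActionKind.SKIP_CREDITS)


def media_position_at(events: Sequence[ActionEvent], t: float):
    """(content, media position) at wall time t by full replay, or None.

    Replays every player event up to t, advancing the media clock
    second-for-second while playing and freezing it while paused; seeks
    jump to their stamped target.  Trusts stamped positions absolutely.
    """
    state = None  # None | "playing" | "paused"
    content = None
    media = None  # position at t_ref
    t_ref = None
    for e in sorted((e for e in events if e.kind in
                     (ActionKind.PLAY, ActionKind.PAUSE, *_SEEKS)), key=lambda x: x.t):
        if e.t > t:
            break
        if state == "playing" and media is not None:
            media += e.t - t_ref
        t_ref = e.t
        if e.kind is ActionKind.PLAY:
            if e.media_pos_s is not None:
                media = e.media_pos_s
            elif e.content is not None and content is not None and e.content != content:
                media = None
            state = "playing"
        elif e.kind is ActionKind.PAUSE:
            if state is None:
                t_ref = None
                continue
            if e.media_pos_s is not None:
                media = e.media_pos_s
            state = "paused"
        else:
            if state is None:
                t_ref = None
                continue
            media = e.media_pos_s
        if e.content is not None:
            content = e.content
    if state is None or t_ref is None:
        return None
    m = media
    if state == "playing" and media is not None:
        m = media + (t - t_ref)
    if content is None or m is None:
        return None
    return content, m


def per_second_coverage(
    start: float,
    effective_end: float,
    watch_start: float | None,
    playing: Sequence[tuple[float, float]],
    buckets: Iterable[int],
):
    """DC/DT/CC/CT percentages by per-second enumeration.

    A second k belongs to a half-open window [s, e) iff s <= k < e; CC/CT
    additionally require k to fall in a playing interval.  Returns a dict
    with None where a metric is undefined.
    """
    kept = set(buckets)

    def pct(lo, hi, restrict):
        exp = obs = 0
        for k in range(math.ceil(lo), math.ceil(hi)):
            if restrict and not any(a <= k < b for a, b in playing):
                continue
            exp += 1
            if k in kept:
                obs += 1
        return 100.0 * obs / exp if exp > 0 else None

    out = {
        "dc": pct(start, effective_end, False),
        "dt": None, "cc": None, "ct": None,
    }
    if playing:
        out["cc"] = pct(start, effective_end, True)
    if watch_start is not None:
        out["dt"] = pct(watch_start, effective_end, False)
        if playing:
            out["ct"] = pct(watch_start, effective_end, True)
    return out
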