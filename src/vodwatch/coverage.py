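"""Session-level physiological coverage metrics on the 1 Hz sampling grid.

The wearable emits nominally one record per second, so coverage is counted
in integer-second *buckets*: a bucket k belongs to a half-open wall-clock
window [s, e) iff s ≤ k < e (equivalently ceil(s) ≤ k < e), and a sample at
time t occupies bucket floor(t).  A one-hour window therefore expects
exactly 3600 buckets.  The same bucket rule is used everywhere — expected
counts, observed counts, gaps and the brute-force test oracles — so the
four metrics are exact integer ratios, not approximations.

The four metrics, all percentages of observed over expected buckets:

* **DC** (data coverage)      — window [session start, effective end).
* **DT** (data transmission)  — window [watch "Start" press, effective end);
  missing when the press time is unknown.
* **CC** (content coverage)   — DC restricted to wall-clock time during
  which content was actually playing.
* **CT** (content transmission) — CC on the DT window.

The watch-start is deliberately not clamped to the session start: a watch
started early enlarges the DT window, reading the definition literally from
the moment of the press.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .events_io import PhysioSample
from .playback import Timeline, playing_intervals
from .sessionize import Session

__all__ = [
    "Gap",
    "CoverageReport",
    "expected_samples",
    "observed_buckets",
    "find_gaps",
    "compute_coverage",
    "GAP_MIN_S",
]

Interval = tuple[float, float]

#: Minimum run of missing buckets (s) reported as a gap.  A single missing
#: second at 1 Hz is transmission jitter; observed real gaps start at 1 s,
#: so this is configurable down to 1.
GAP_MIN_S = 2


@dataclass(frozen=True)
class Gap:
    """A maximal run of unobserved buckets inside a coverage window.

    Coordinates are on the integer bucket grid (half-open).  ``terminal``
    marks a gap that reaches the window end — the stream died and never
    recovered.
    """

    start_t: float
    end_t: float
    terminal: bool

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


@dataclass
class CoverageReport:
    """DC/DT/CC/CT counts and percentages plus the gap list for one session.

    A pct is None when its expected count is zero or its window is
    undefined (no watch-start for DT/CT, no playback for CC/CT).
    """

    session_id: str
    window_dc: Interval
    window_dt: Interval | None
    expected_dc: int = 0
    observed_dc: int = 0
    expected_dt: int = 0
    observed_dt: int = 0
    expected_cc: int = 0
    observed_cc: int = 0
    expected_ct: int = 0
    observed_ct: int = 0
    dc_pct: float | None = None
    dt_pct: float | None = None
    cc_pct: float | None = None
    ct_pct: float | None = None
    gaps: list[Gap] = field(default_factory=list)
    has_hr: bool = False


def expected_samples(window: Interval) -> int:
    """Number of 1 Hz emission slots in a half-open wall-clock window.

    Counts integer seconds k with ceil(start) ≤ k < end; [0, 3600) → 3600.
    """
    s, e = window
    if e <= s:
        return 0
    return max(0, math.ceil(e) - math.ceil(s))


def _bucket_array(samples: Sequence[PhysioSample]) -> np.ndarray:
    """Sorted unique integer buckets occupied by samples carrying signal."""
    ks = [math.floor(s.t) for s in samples if s.has_signal]
    if not ks:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.asarray(ks, dtype=np.int64))


def _count_in(buckets: np.ndarray, window: Interval) -> int:
    s, e = window
    if e <= s:
        return 0
    lo = np.searchsorted(buckets, math.ceil(s), side="left")
    hi = np.searchsorted(buckets, math.ceil(e), side="left")
    return int(hi - lo)


def observed_buckets(samples: Sequence[PhysioSample], window: Interval) -> int:
    """Distinct occupied buckets inside the window (duplicates count once)."""
    return _count_in(_bucket_array(samples), window)


def _intersect(intervals: Sequence[Interval], window: Interval) -> list[Interval]:
    s, e = window
    out = []
    for a, b in intervals:
        lo, hi = max(a, s), min(b, e)
        if hi > lo:
            out.append((lo, hi))
    return out


def find_gaps(
    samples: Sequence[PhysioSample], window: Interval, gap_min_s: int = GAP_MIN_S
) -> list[Gap]:
    """Maximal runs of ≥ ``gap_min_s`` unobserved buckets in the window.

    Gap coordinates lie on the bucket grid; with ``gap_min_s=1`` the gap
    durations and the observed count partition the expected count exactly.
    """
    s, e = window
    k0, k1 = math.ceil(s), math.ceil(e)
    if k1 <= k0:
        return []
    buckets = _bucket_array(samples)
    lo = np.searchsorted(buckets, k0, side="left")
    hi = np.searchsorted(buckets, k1, side="left")
    obs = buckets[lo:hi]
    edges = np.concatenate(([k0 - 1], obs, [k1]))
    gaps: list[Gap] = []
    for i in range(len(edges) - 1):
        run_start = int(edges[i]) + 1
        run_end = int(edges[i + 1])  # exclusive
        if run_end - run_start >= gap_min_s:
            gaps.append(Gap(
                start_t=float(run_start), end_t=float(run_end),
                terminal=(run_end == k1),
            ))
    return gaps


def compute_coverage(
    session: Session,
    timeline: Timeline | None,
    samples: Sequence[PhysioSample],
    gap_min_s: int = GAP_MIN_S,
) -> CoverageReport:
    """All four coverage metrics plus the gap structure for one session.

    Requires an imputed effective end; ``samples`` should be the
    participant's stream (any device).  CC/CT are undefined for sessions
    with no playback; DT/CT are undefined without a watch-start.
    """
    if session.effective_end_t is None:
        raise ValueError("compute_coverage requires effective_end_t")
    win_dc: Interval = (session.start_t, session.effective_end_t)
    win_dt: Interval | None = None
    if session.watch_start_t is not None:
        win_dt = (session.watch_start_t, session.effective_end_t)

    buckets = _bucket_array(samples)
    playing = playing_intervals(timeline) if timeline is not None else []

    def counts(window: Interval | None, restrict: bool) -> tuple[int, int]:
        if window is None:
            return 0, 0
        parts = _intersect(playing, window) if restrict else [window]
        exp = sum(expected_samples(p) for p in parts)
        obs = sum(_count_in(buckets, p) for p in parts)
        return exp, obs

    exp_dc, obs_dc = counts(win_dc, restrict=False)
    exp_dt, obs_dt = counts(win_dt, restrict=False)
    exp_cc, obs_cc = counts(win_dc if playing else None, restrict=True)
    exp_ct, obs_ct = counts(win_dt if playing else None, restrict=True)

    def pct(obs: int, exp: int) -> float | None:
        return 100.0 * obs / exp if exp > 0 else None

    hr_ks = [math.floor(s.t) for s in samples if s.hr_bpm is not None]
    has_hr = any(win_dc[0] <= k < win_dc[1] for k in hr_ks)

    return CoverageReport(
        session_id=session.session_id,
        window_dc=win_dc, window_dt=win_dt,
        expected_dc=exp_dc, observed_dc=obs_dc,
        expected_dt=exp_dt, observed_dt=obs_dt,
        expected_cc=exp_cc, observed_cc=obs_cc,
        expected_ct=exp_ct, observed_ct=obs_ct,
        dc_pct=pct(obs_dc, exp_dc), dt_pct=pct(obs_dt, exp_dt),
        cc_pct=pct(obs_cc, exp_cc), ct_pct=pct(obs_ct, exp_ct),
        gaps=find_gaps(samples, win_dc, gap_min_s=gap_min_s),
        has_hr=has_hr,
    )
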