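# Methods

This note documents the models, rules and numerical conventions behind
vodwatch, the defaults and why they were chosen, and what the synthetic
studies do and do not establish about real data.

## Time and the 1 Hz grid

Timestamps are UTC epoch seconds internally; all time-zone handling lives
at the reader boundary (readers accept epoch numbers or ISO-8601 in any
zone). The wearable emits nominally one record per second, so every
coverage computation is carried out on the integer-second grid with one
rule stated once and reused everywhere:

* a bucket *k* (an integer second) belongs to the half-open window
  [s, e) iff s ≤ k < e — equivalently ⌈s⌉ ≤ k < e;
* a sample at time *t* occupies bucket ⌊t⌋; duplicates in a bucket count
  once; samples carrying no physiological field count never.

All four metrics are exact integer ratios under this rule, which is why
the test suite can demand bit-exact agreement with per-second brute-force
enumeration rather than tolerance bands. JSON-Lines event files store the
epoch number directly so a write/read cycle is bit-exact; the CSV dialects
store ISO-8601 UTC for human readability.

## Session model

Sessions are bracket-matched per participant from the tab open/close
boundary events. Decisions in the genuinely open corners:

* **Content means playback.** A session with searches but no play event is
  *empty*: browsing and login-only visits are normal user behaviour, not
  viewing.
* **A new open force-closes an unclosed session.** Viewers sometimes close
  the tab hours or days later (or never, offline); overlapping sessions
  for one participant are not meaningful, so the earlier session is closed
  as a semi-valid candidate and flagged.
* **Effective end of a semi-valid session** is the last pause; if the
  stream ends mid-play (no pause after the last play) the last recorded
  action of any kind stands in and the session is flagged
  `no_terminating_pause`. Sessions with an observed close always use it.
* **No content and no close** is folded into *empty* with a flag rather
  than minted as a fourth class.
* **Watch start resolution**: the latest smartwatch Start press at or
  before the effective end; failing that, the first physiological sample
  within a 600 s look-back from the session start (bounded so a session
  recorded without the watch cannot inherit a stale stream from hours
  earlier); failing both, the transmission metrics (DT/CT) are reported
  missing. The watch start is deliberately *not* clamped to the session
  start — the transmission window reads literally from the press.

## Playback state machine

Two states (PLAYING, PAUSED) over the in-player events; playback rate is
fixed at 1.0 because the action vocabulary has no speed control. Seeks and
skips reposition the media clock instantaneously and preserve the state
(seeking does not toggle play/pause on the player). Segments are half-open
in wall time, contiguous from the first play to the effective end, giving
the conservation law

    Σ playing + Σ paused = effective_end − first_play   (exactly),

which the suite asserts on every fixture. Stamped media positions are
trusted over projections — the collection extension read them from the
player — and a pause whose stamp disagrees with the projection by more
than `drift_tol_s = 2 s` wins the argument and leaves a drift anomaly.
A skip with no stamped target advances to an unknown position: those
seconds still count as playing wall time but are excluded from media
mapping.

Two episode-switch faults observed in real collections are repaired before
timeline construction, each repair recorded: an event with no content
during active playback inherits the content of the nearest following
content-bearing event within `repair_window_s = 10 s` (else the current
state's content, else it stays empty and flagged); an event whose stamped
position exceeds its episode's known runtime is a stale stamp, flagged and
reattributed to the next episode when one follows within the window.

## QA thresholds

| parameter | default | unit | rationale |
|---|---|---|---|
| `gap_min_s` | 2 | s | one missing second at 1 Hz is jitter; real gaps start at 1 s, so this is configurable down to 1 |
| `presession_window_s` | 5 | s | the live pre-session presence check looked back five seconds |
| `period_s` | 300 | s | the periodic stream verification ran every five minutes; tiles are aligned to the window start (the original's alignment is unstated) |
| `battery_threshold_pct` | 15 | % | the low-battery alert has no published level; 15% leaves roughly 3–4 h of margin at observed drain rates |
| `terminal_dropout_min_s` | 120 | s | observed recoverable gaps ranged 1 s–2 min; anything terminal beyond that ceiling never recovered |
| `drift_tol_s` | 2 | s | one grid step of slack on either side of a stamped position |

The alarms ran live during collection in the original tooling; here they
are offline re-checks with identical predicates and different delivery.

## Simulator

The generator emulates evening at-home viewing: per participant-night one
session that is empty (probability 0.35), else semi-valid (0.2) or valid,
with episodes of mean length 2543 s (≈ 42 m 23 s, the observed mean of
binge-watched episodes) watched three-in-a-row by default (binge arm; set
`episodes_per_session=1` for the one-per-night control arm). Pauses
(2/h, mean 60 s) and seeks (1.5/h) arrive as a Poisson process on playing
time; intro skips and credit skips occur with probabilities 0.4 and 0.5.
The empty-session and semi-valid rates sit between the arms observed in
real deployments (empty ≈ 0.38 and ≈ 0.39; semi-valid ≈ 0.54 and ≈ 0.05),
biased toward the better-behaved arm. The watch starts a half-minute
(mean 30 s, sd 10 s, floor 5 s) before the session opens and stops shortly
after it ends.

Heart rate is an AR(1) fluctuation (baseline 72 bpm, sd 6, coefficient
0.97) around rest; inertial axes are noise around gravity. Coverage
accounting depends only on sample *presence*, so no cardiac realism is
claimed and none should be inferred. Battery drains linearly at 4%/h from
a 60–100% start.

Fault families (all off by default), each recorded in an exact inventory:
i.i.d. per-second sample loss; contiguous recoverable gaps with durations
uniform in 1–120 s; terminal dropout at a uniform cut in the second half
of the stream; empty-content stamps on episode-transition plays; stale
stamps (previous episode's identity with a position past its runtime) on
the same transitions; and same-timestamp disorder. Disorder is injected
only on timing-neutral events (a session's search is collapsed onto its
open marker and emitted in the wrong order) so the behavioural ground
truth — playing intervals, session ends — is untouched by construction.

Ground-truth coverage fractions are computed inside the generator by
per-second enumeration from its own records, independently of the
pipeline's interval arithmetic; their exact agreement is the core
correctness check.

**What passing does not show.** The simulator emulates the *structure* of
real collections (session taxonomy, 1 Hz emission, the documented fault
modes), not real behaviour: no circadian or emotional heart-rate response,
no multitasking, no content-driven pausing patterns, and fault rates are
stationary. Exact metric agreement demonstrates the accounting is right,
not that real streams are this well behaved.

## Problem sizes

The oracle-equivalence check runs 1000 simulated sessions of ≤ 2 h
(50 independent 20-session studies); missingness recovery uses 100
one-hour sessions at 10% per-second loss, asserting the mean DC within
three standard errors of 90% — a seeded statistical check, not a
tolerance; fault detection pools ~100 injected faults across families.
The acceptance script uses 400 sessions for the oracle sweep and the same
sizes elsewhere.

## Known limitations

* Segmentation trusts the boundary markers; a participant with two
  browsers open concurrently would be serialized, not parallelized.
* Stale-stamp detection needs the episode runtime from metadata; without
  it the fault is invisible until an episode switch repairs it.
* CC counts playing *wall* seconds, not distinct media seconds; a viewer
  re-watching a scene counts the wall time twice. Pauses are excluded by
  definition, which is the reading that makes CC collapse to DC when the
  whole window is playing time.
* The per-session figure fixes its data layers (heart-rate trace, playing
  bands, gap shading, action markers); its styling is unspecified and
  untested.
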