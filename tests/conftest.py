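"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from vodwatch.events_io import ActionEvent, ActionKind, ContentRef, PhysioSample

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


EP1 = ContentRef(title_id="show", episode_id="s01e01", runtime_s=2520.0)
EP2 = ContentRef(title_id="show", episode_id="s01e02", runtime_s=2520.0)


def ev(kind, t, pid="p1", content=None, pos=None, seq=None) -> ActionEvent:
    """Shorthand event builder used across the suite."""
    return ActionEvent(
        participant_id=pid, t=float(t), kind=ActionKind[kind],
        content=content, media_pos_s=pos, source_seq=seq,
    )


def sample(t, pid="p1", device="w1", hr=75.0, battery=None) -> PhysioSample:
    return PhysioSample(
        participant_id=pid, device_id=device, t=float(t),
        hr_bpm=hr, battery_pct=battery,
    )


def samples_at(buckets, pid="p1", **kw) -> list[PhysioSample]:
    """One sample per listed integer second."""
    return [sample(k, pid=pid, **kw) for k in buckets]


@pytest.fixture
def ep1():
    return EP1


@pytest.fixture
def ep2():
    return EP2
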