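"""Pipeline configuration: every analysis threshold in one structure.

All thresholds are plain numbers with documented units so a study
configuration can be carried in a single YAML file and exported alongside
results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .coverage import GAP_MIN_S
from .playback import DRIFT_TOL_S, REPAIR_WINDOW_S
from .qa import (
    BATTERY_THRESHOLD_PCT,
    PERIODIC_PERIOD_S,
    PRESESSION_WINDOW_S,
    TERMINAL_DROPOUT_MIN_S,
)
from .sessionize import WATCH_FALLBACK_LOOKBACK_S

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Analysis thresholds (seconds unless noted)."""

    gap_min_s: int = GAP_MIN_S                      # min missing-bucket run reported as a gap
    drift_tol_s: float = DRIFT_TOL_S                # stamped-vs-projected position tolerance
    repair_window_s: float = REPAIR_WINDOW_S        # stamp-repair look-ahead
    presession_window_s: float = PRESESSION_WINDOW_S
    period_s: float = PERIODIC_PERIOD_S             # periodic stream-verification tile
    battery_threshold_pct: float = BATTERY_THRESHOLD_PCT  # percent
    terminal_dropout_min_s: float = TERMINAL_DROPOUT_MIN_S
    watch_fallback_lookback_s: float = WATCH_FALLBACK_LOOKBACK_S

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        section = data.get("pipeline", data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**section)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"pipeline": dataclasses.asdict(self)}, sort_keys=True),
            encoding="utf-8",
        )
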