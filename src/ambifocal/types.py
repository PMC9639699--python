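"""Shared domain records: trial metadata and segmented eye-movement events.

Events use half-open integer-millisecond intervals ``[onset_ms, offset_ms)``
throughout the package, so a trial's fixations, saccades and blinks can
partition ``[0, trial_duration_ms)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import pandas as pd

CONDITIONS = ("central", "peripheral", "control")
SCENE_TYPES = ("natural", "urban")

#: Canonical event-table column order (the events CSV dialect).
EVENT_COLUMNS = [
    "participant_id",
    "trial_index",
    "event_kind",
    "onset_ms",
    "offset_ms",
    "duration_ms",
    "x_start_px",
    "y_start_px",
    "x_end_px",
    "y_end_px",
    "amplitude_deg",
]


@dataclass
class TrialMeta:
    participant_id: str
    trial_index: int
    condition: str
    scene_type: str
    scene_id: str = ""
    trial_duration_ms: int = 20000

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r} "
                f"(trial {self.participant_id}/{self.trial_index})"
            )
        if self.scene_type not in SCENE_TYPES:
            raise ValueError(
                f"unknown scene_type {self.scene_type!r} "
                f"(trial {self.participant_id}/{self.trial_index})"
            )
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")
        if self.trial_duration_ms <= 0:
            raise ValueError("trial_duration_ms must be > 0")


@dataclass
class Blink:
    onset_ms: int
    offset_ms: int

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("Blink offset must exceed onset")

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass
class Saccade:
    onset_ms: int
    offset_ms: int
    x_start_px: float
    y_start_px: float
    x_end_px: float
    y_end_px: float
    amplitude_deg: float
    peak_velocity_deg_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("Saccade offset must exceed onset")
        if self.amplitude_deg < 0:
            raise ValueError("Saccade amplitude must be >= 0")

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass
class Fixation:
    onset_ms: int
    offset_ms: int
    x_px: float
    y_px: float
    preceding_saccade_amplitude_deg: Optional[float] = None
    label: str = "unclassified"  # {"ambient", "focal", "unclassified"}

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("Fixation offset must exceed onset")

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass
class Trial:
    """One trial's segmented events plus metadata."""

    meta: TrialMeta
    fixations: List[Fixation] = field(default_factory=list)
    saccades: List[Saccade] = field(default_factory=list)
    blinks: List[Blink] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str = ""


def events_to_frame(trials: List[Trial]) -> pd.DataFrame:
    """Flatten Trial objects into the canonical event table."""
    rows = []
    for tr in trials:
        pid, ti = tr.meta.participant_id, tr.meta.trial_index
        for f in tr.fixations:
            rows.append(
                (pid, ti, "fixation", f.onset_ms, f.offset_ms, f.duration_ms,
                 f.x_px, f.y_px, f.x_px, f.y_px, float("nan")))
        for s in tr.saccades:
            rows.append(
                (pid, ti, "saccade", s.onset_ms, s.offset_ms, s.duration_ms,
                 s.x_start_px, s.y_start_px, s.x_end_px, s.y_end_px, s.amplitude_deg))
        for b in tr.blinks:
            rows.append(
                (pid, ti, "blink", b.onset_ms, b.offset_ms, b.duration_ms,
                 float("nan"), float("nan"), float("nan"), float("nan"), float("nan")))
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return frame.sort_values(
        ["participant_id", "trial_index", "onset_ms", "event_kind"]
    ).reset_index(drop=True)


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "trial_index": pd.Series(dtype=int),
            "event_kind": pd.Series(dtype=str),
            "onset_ms": pd.Series(dtype=int),
            "offset_ms": pd.Series(dtype=int),
            "duration_ms": pd.Series(dtype=int),
            "x_start_px": pd.Series(dtype=float),
            "y_start_px": pd.Series(dtype=float),
            "x_end_px": pd.Series(dtype=float),
            "y_end_px": pd.Series(dtype=float),
            "amplitude_deg": pd.Series(dtype=float),
        }
    )
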