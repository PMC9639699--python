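"""Readers and writers for the package's plain-text data dialects.

Three tables move through the pipeline:

* **samples CSV** — raw gaze streams, one row per 1-ms sample, header
  ``participant_id,trial_index,condition,scene_type,t_ms,x_px,y_px,pupil``.
* **events CSV** — segmented fixations/saccades/blinks, header per
  :data:`ambifocal.types.EVENT_COLUMNS`.
* **manifest CSV** — trial metadata, header
  ``participant_id,trial_index,condition,scene_type,scene_id``.

A tolerant reader for a minimal EyeLink-ASC-like text subset is also
provided: sample lines are ``t<TAB>x<TAB>y<TAB>pupil`` and a line
``MSG <t> TRIALID <participant>_<trial>_<condition>_<scenetype>`` opens a
trial whose samples are re-based to that timestamp. Native event lines
(EFIX/ESACC/EBLINK and friends) are ignored — events are re-detected from
samples, never trusted from the recording.

Missing x/y/pupil fields are encoded as ``.`` (or an empty field) and
decoded to NaN. Timestamps must be integral milliseconds; fractional
timestamps are rejected rather than silently rounded, because rounding
hides sample-rate errors.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .types import CONDITIONS, EVENT_COLUMNS, SCENE_TYPES, TrialMeta, empty_events

logger = logging.getLogger(__name__)

SAMPLES_COLUMNS = [
    "participant_id",
    "trial_index",
    "condition",
    "scene_type",
    "t_ms",
    "x_px",
    "y_px",
    "pupil",
]
MANIFEST_COLUMNS = ["participant_id", "trial_index", "condition", "scene_type", "scene_id"]

MISSING = "."

Source = Union[str, io.TextIOBase]


@dataclass
class TrialSamples:
    """One trial's ordered gaze samples plus its metadata."""

    meta: TrialMeta
    samples: pd.DataFrame  # columns t_ms (int), x_px, y_px, pupil (float, NaN = missing)


def _open(source: Source, mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, encoding="utf-8", newline=""), True


def _parse_float(tok: str) -> float:
    tok = tok.strip()
    if tok in ("", MISSING):
        return math.nan
    return float(tok)


def _check_trial_samples(pid: str, trial: int, t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ValueError(f"negative timestamp in trial ({pid},{trial})")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"non-monotone timestamps in trial ({pid},{trial})")


def read_samples(source: Source, dialect: str = "csv") -> Dict[Tuple[str, int], TrialSamples]:
    """Read gaze sample streams grouped per (participant_id, trial_index).

    Parameters
    ----------
    source : path or text stream
    dialect : {"csv", "asc_subset"}

    Returns
    -------
    dict mapping (participant_id, trial_index) -> TrialSamples.
    An empty stream yields an empty map.
    """
    if dialect == "csv":
        return _read_samples_csv(source)
    if dialect == "asc_subset":
        return _read_samples_asc(source)
    raise ValueError(f"unknown samples dialect {dialect!r}")


def _read_samples_csv(source: Source) -> Dict[Tuple[str, int], TrialSamples]:
    fh, close = _open(source)
    try:
        frame = pd.read_csv(
            fh,
            dtype={"participant_id": str, "condition": str, "scene_type": str},
            na_values=[MISSING],
            keep_default_na=True,
        )
    except pd.errors.EmptyDataError:
        return {}
    finally:
        if close:
            fh.close()
    if frame.empty:
        return {}
    missing_cols = [c for c in SAMPLES_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"samples CSV missing columns {missing_cols}")

    t = frame["t_ms"].to_numpy(dtype=float)
    if np.any(t != np.floor(t)):
        raise ValueError("fractional t_ms timestamps are not allowed")
    frame["t_ms"] = t.astype(np.int64)

    out: Dict[Tuple[str, int], TrialSamples] = {}
    for (pid, trial), grp in frame.groupby(["participant_id", "trial_index"], sort=True):
        trial = int(trial)
        tarr = grp["t_ms"].to_numpy()
        _check_trial_samples(pid, trial, tarr)
        cond = grp["condition"].iloc[0]
        scene = grp["scene_type"].iloc[0]
        spacing = int(np.median(np.diff(tarr))) if len(tarr) > 1 else 1
        meta = TrialMeta(
            participant_id=pid,
            trial_index=trial,
            condition=cond,
            scene_type=scene,
            trial_duration_ms=int(tarr[-1]) + spacing,
        )
        samples = grp[["t_ms", "x_px", "y_px", "pupil"]].reset_index(drop=True)
        out[(pid, trial)] = TrialSamples(meta=meta, samples=samples)
    return out


_TRIALID_RE = re.compile(r"^MSG\s+(\d+)\s+TRIALID\s+(\S+)\s*$")
_IGNORED_RE = re.compile(r"^(EFIX|ESACC|EBLINK|SFIX|SSACC|SBLINK|START|END|INPUT|MSG)\b")


def _read_samples_asc(source: Source) -> Dict[Tuple[str, int], TrialSamples]:
    fh, close = _open(source)
    out: Dict[Tuple[str, int], TrialSamples] = {}
    cur_key: Optional[Tuple[str, int]] = None
    cur_meta: Optional[TrialMeta] = None
    cur_onset = 0
    rows: List[Tuple[int, float, float, float]] = []

    def flush() -> None:
        nonlocal rows
        if cur_key is None:
            return
        if not rows:
            rows = []
            return
        t = np.array([r[0] for r in rows], dtype=np.int64)
        _check_trial_samples(cur_key[0], cur_key[1], t)
        spacing = int(np.median(np.diff(t))) if len(t) > 1 else 1
        cur_meta.trial_duration_ms = int(t[-1]) + spacing
        out[cur_key] = TrialSamples(
            meta=cur_meta,
            samples=pd.DataFrame(rows, columns=["t_ms", "x_px", "y_px", "pupil"]),
        )
        rows = []

    try:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            m = _TRIALID_RE.match(line)
            if m:
                flush()
                onset = int(m.group(1))
                token = m.group(2)
                parts = token.rsplit("_", 3)
                if len(parts) != 4:
                    raise ValueError(f"malformed TRIALID token {token!r}")
                pid, trial_s, cond, scene = parts
                cur_key = (pid, int(trial_s))
                cur_onset = onset
                cur_meta = TrialMeta(
                    participant_id=pid,
                    trial_index=int(trial_s),
                    condition=cond,
                    scene_type=scene,
                )
                continue
            if _IGNORED_RE.match(line):
                logger.debug("ignoring recorder event line: %s", line)
                continue
            fields = line.split("\t")
            if cur_key is None:
                logger.debug("sample line before any TRIALID, ignored: %s", line)
                continue
            if len(fields) < 4:
                logger.debug("unparseable line ignored: %s", line)
                continue
            tok = fields[0].strip()
            try:
                t_abs = float(tok)
            except ValueError:
                logger.debug("unparseable line ignored: %s", line)
                continue
            if t_abs != math.floor(t_abs):
                raise ValueError(f"fractional timestamp {tok!r} is not allowed")
            rows.append(
                (
                    int(t_abs) - cur_onset,
                    _parse_float(fields[1]),
                    _parse_float(fields[2]),
                    _parse_float(fields[3]),
                )
            )
        flush()
    finally:
        if close:
            fh.close()
    return out


def write_samples(trials: Dict[Tuple[str, int], TrialSamples], sink: Source) -> None:
    """Write trial sample streams in the samples CSV dialect (LF, UTF-8)."""
    fh, close = _open(sink, "w")
    try:
        fh.write(",".join(SAMPLES_COLUMNS) + "\n")
        for key in sorted(trials):
            ts = trials[key]
            meta = ts.meta
            for t_ms, x, y, p in ts.samples[["t_ms", "x_px", "y_px", "pupil"]].itertuples(index=False):
                fh.write(
                    f"{meta.participant_id},{meta.trial_index},{meta.condition},"
                    f"{meta.scene_type},{int(t_ms)},{_fmt_px(x)},{_fmt_px(y)},{_fmt_px(p)}\n"
                )
    finally:
        if close:
            fh.close()


def _fmt_px(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return MISSING
    return format(float(v), ".6g")


def _fmt_deg(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return format(float(v), ".6g")


def write_events(events: pd.DataFrame, sink: Source) -> None:
    """Write an event table in the canonical dialect.

    Column order is fixed; millisecond fields are integers and degree/pixel
    fields use 6 significant digits. Rows violating ``offset > onset`` raise
    before any output is produced.
    """
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise ValueError(f"event table missing column {col!r}")
    if len(events):
        bad = events["offset_ms"].to_numpy() <= events["onset_ms"].to_numpy()
        if bad.any():
            raise ValueError(f"{int(bad.sum())} event rows violate offset_ms > onset_ms")
        dur = events["offset_ms"].to_numpy() - events["onset_ms"].to_numpy()
        if np.any(dur != events["duration_ms"].to_numpy()):
            raise ValueError("duration_ms must equal offset_ms - onset_ms")
    fh, close = _open(sink, "w")
    try:
        fh.write(",".join(EVENT_COLUMNS) + "\n")
        for row in events[EVENT_COLUMNS].itertuples(index=False):
            (pid, trial, kind, onset, offset, dur, xs, ys, xe, ye, amp) = row
            fh.write(
                f"{pid},{int(trial)},{kind},{int(onset)},{int(offset)},{int(dur)},"
                f"{_fmt_px(xs)},{_fmt_px(ys)},{_fmt_px(xe)},{_fmt_px(ye)},{_fmt_deg(amp)}\n"
            )
    finally:
        if close:
            fh.close()


def read_events(source: Source) -> pd.DataFrame:
    """Read an events CSV back into the canonical table."""
    fh, close = _open(source)
    try:
        frame = pd.read_csv(
            fh, dtype={"participant_id": str, "event_kind": str},
            na_values=[MISSING, ""], keep_default_na=True,
        )
    except pd.errors.EmptyDataError:
        return empty_events()
    finally:
        if close:
            fh.close()
    if frame.empty:
        return empty_events()
    missing_cols = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"events CSV missing columns {missing_cols}")
    for col in ("trial_index", "onset_ms", "offset_ms", "duration_ms"):
        frame[col] = frame[col].astype(np.int64)
    for col in ("x_start_px", "y_start_px", "x_end_px", "y_end_px", "amplitude_deg"):
        frame[col] = frame[col].astype(float)
    return frame[EVENT_COLUMNS]


def read_manifest(source: Source, strict: bool = False) -> List[TrialMeta]:
    """Read a trial manifest.

    In strict mode each participant must have 90 trials: 30 per condition
    with 15 natural and 15 urban scenes inside each condition (the study's
    design); deviations raise a ValueError listing every offending count.
    Lax mode accepts any counts. An empty file yields an empty list.
    """
    fh, close = _open(source)
    try:
        frame = pd.read_csv(fh, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    finally:
        if close:
            fh.close()
    if frame.empty:
        return []
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"manifest CSV missing columns {missing_cols}")
    metas = [
        TrialMeta(
            participant_id=r.participant_id,
            trial_index=int(r.trial_index),
            condition=r.condition,
            scene_type=r.scene_type,
            scene_id=("" if pd.isna(r.scene_id) else r.scene_id),
        )
        for r in frame.itertuples(index=False)
    ]
    if strict:
        validate_manifest(metas)
    return metas


def validate_manifest(metas: List[TrialMeta]) -> None:
    """Enforce the 90 = 3 x (15 natural + 15 urban) per-participant design."""
    frame = pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in metas],
            "condition": [m.condition for m in metas],
            "scene_type": [m.scene_type for m in metas],
        }
    )
    problems = []
    for pid, grp in frame.groupby("participant_id", sort=True):
        if len(grp) != 90:
            problems.append(f"{pid}: {len(grp)} trials (expected 90)")
        for cond in CONDITIONS:
            sub = grp[grp["condition"] == cond]
            if len(sub) != 30:
                problems.append(f"{pid}/{cond}: {len(sub)} trials (expected 30)")
            for scene in SCENE_TYPES:
                n = int((sub["scene_type"] == scene).sum())
                if n != 15:
                    problems.append(f"{pid}/{cond}/{scene}: {n} trials (expected 15)")
    if problems:
        raise ValueError("manifest validation failed: " + "; ".join(problems))


def write_manifest(metas: List[TrialMeta], sink: Source) -> None:
    fh, close = _open(sink, "w")
    try:
        fh.write(",".join(MANIFEST_COLUMNS) + "\n")
        for m in metas:
            fh.write(
                f"{m.participant_id},{m.trial_index},{m.condition},{m.scene_type},{m.scene_id}\n"
            )
    finally:
        if close:
            fh.close()


def manifest_frame(metas: List[TrialMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in metas],
            "trial_index": [m.trial_index for m in metas],
            "condition": [m.condition for m in metas],
            "scene_type": [m.scene_type for m in metas],
            "scene_id": [m.scene_id for m in metas],
        }
    )
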