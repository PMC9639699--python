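"""Event detection: blinks, saccades and fixations from raw gaze samples.

The detector mirrors the online parser used with 1000 Hz video-based eye
trackers. Pixel positions are converted to degrees, lightly smoothed with a
boxcar, and differentiated with 2-point central differences to give speed
(deg/s) and its derivative (deg/s^2). A saccade candidate opens at the first
sample whose speed exceeds ``min_velocity_deg_s`` OR whose |acceleration|
exceeds ``min_accel_deg_s2``; it must stay above threshold for at least
``min_sustain_ms``; it closes at the first subsequent sample where speed is
below the velocity threshold AND |acceleration| is below the acceleration
threshold. Completed candidates are kept only if the start-to-end deflection
exceeds ``min_deflection_deg``, and candidates overlapping a blink are
discarded. Fixations are the complement of saccades and blinks over the
trial, so the three event kinds partition the trial exactly.

Defaults are the study's published thresholds: 30 deg/s, 8000 deg/s^2,
4 ms sustain, 0.1 deg deflection.

All intervals are half-open ``[onset_ms, offset_ms)`` in integer
milliseconds, and saccade amplitude is the angular distance from the onset
sample to the first post-saccade sample (not the peak excursion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import MaskSpec, ScreenGeometry, angular_distance, px_to_deg, visible  # noqa: F401
from .io_formats import TrialSamples
from .types import Blink, Fixation, Saccade, Trial, TrialMeta, events_to_frame

__all__ = [
    "DetectionParams",
    "detect_blinks",
    "compute_kinematics",
    "detect_saccades",
    "segment_fixations",
    "detect_trial",
    "SaccadeDetector",
]


@dataclass
class DetectionParams:
    """Thresholds for the velocity/acceleration saccade parser."""

    min_deflection_deg: float = 0.1
    min_velocity_deg_s: float = 30.0
    min_accel_deg_s2: float = 8000.0
    min_sustain_ms: float = 4.0
    velocity_smooth_ms: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "min_deflection_deg",
            "min_velocity_deg_s",
            "min_accel_deg_s2",
            "min_sustain_ms",
            "velocity_smooth_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"DetectionParams.{name} must be strictly positive")


def detect_blinks(samples: pd.DataFrame, merge_gap_ms: int = 0) -> List[Blink]:
    """Maximal runs of samples with missing (NaN or 0) pupil become blinks.

    Runs separated by <= ``merge_gap_ms`` are merged. The default of 0
    performs no merging, matching a literal reading of "periods in which
    pupil information was missing". Offsets are half-open: a dropout over
    samples 5000..5120 ms yields Blink(5000, 5121).
    """
    t = samples["t_ms"].to_numpy()
    pupil = samples["pupil"].to_numpy(dtype=float)
    missing = np.isnan(pupil) | (pupil == 0.0)
    if not missing.any():
        return []
    dt = int(np.median(np.diff(t))) if len(t) > 1 else 1
    padded = np.concatenate(([False], missing, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    intervals = [(int(t[s]), int(t[e - 1]) + dt) for s, e in zip(starts, ends)]
    merged: List[Tuple[int, int]] = [intervals[0]]
    for on, off in intervals[1:]:
        if on - merged[-1][1] <= merge_gap_ms:
            merged[-1] = (merged[-1][0], off)
        else:
            merged.append((on, off))
    return [Blink(on, off) for on, off in merged]


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Boxcar smoothing with edge replication; NaNs propagate."""
    if width <= 1:
        return x.copy()
    pad = width // 2
    xp = np.concatenate((np.repeat(x[0], pad), x, np.repeat(x[-1], width - 1 - pad)))
    kernel = np.ones(width) / width
    return np.convolve(xp, kernel, mode="valid")


def compute_kinematics(
    samples: pd.DataFrame,
    geometry: ScreenGeometry,
    params: DetectionParams,
    blinks: Optional[List[Blink]] = None,
) -> pd.DataFrame:
    """Per-sample 2D speed (deg/s) and tangential acceleration (deg/s^2).

    Positions are converted to degrees, boxcar-smoothed over
    ``velocity_smooth_ms``, and differentiated with central differences
    (endpoints replicated). Samples inside blinks yield NaN kinematics.

    Raises on fewer than 5 samples or non-uniform sampling.
    """
    t = samples["t_ms"].to_numpy()
    if len(t) < 5:
        raise ValueError("compute_kinematics requires at least 5 samples")
    dt_all = np.diff(t)
    if not np.all(dt_all == dt_all[0]):
        raise ValueError("non-uniform sampling: kinematics require constant spacing")
    dt_ms = int(dt_all[0])
    expected = geometry.sample_spacing_ms
    if abs(dt_ms - expected) > 1e-9:
        raise ValueError(
            f"sample spacing {dt_ms} ms does not match geometry sample rate "
            f"({expected} ms expected)"
        )
    dt_s = dt_ms / 1000.0

    x_deg, y_deg = px_to_deg(
        samples["x_px"].to_numpy(dtype=float), samples["y_px"].to_numpy(dtype=float), geometry
    )
    if blinks:
        in_blink = np.zeros(len(t), dtype=bool)
        for b in blinks:
            in_blink |= (t >= b.onset_ms) & (t < b.offset_ms)
        x_deg = np.where(in_blink, np.nan, x_deg)
        y_deg = np.where(in_blink, np.nan, y_deg)

    width = max(1, int(round(params.velocity_smooth_ms / dt_ms)))
    xs = _smooth(x_deg, width)
    ys = _smooth(y_deg, width)

    def central_diff(v: np.ndarray, step: float) -> np.ndarray:
        d = np.empty_like(v)
        d[1:-1] = (v[2:] - v[:-2]) / (2.0 * step)
        d[0], d[-1] = d[1], d[-2]
        return d

    vx = central_diff(xs, dt_s)
    vy = central_diff(ys, dt_s)
    speed = np.hypot(vx, vy)
    accel = central_diff(speed, dt_s)
    return pd.DataFrame(
        {"t_ms": t, "x_deg": x_deg, "y_deg": y_deg, "speed_deg_s": speed, "accel_deg_s2": accel}
    )


def detect_saccades(
    samples: pd.DataFrame,
    geometry: ScreenGeometry,
    params: DetectionParams,
    blinks: Optional[List[Blink]] = None,
) -> List[Saccade]:
    """Segment saccades with the velocity/acceleration/deflection criteria.

    Returns time-ordered, non-overlapping saccades; an empty list when no
    sample crosses threshold.
    """
    kin = compute_kinematics(samples, geometry, params, blinks=blinks)
    t = kin["t_ms"].to_numpy()
    dt_ms = int(t[1] - t[0])
    speed = kin["speed_deg_s"].to_numpy()
    accel = kin["accel_deg_s2"].to_numpy()
    # NaN compares False, so blink samples never open or sustain a candidate.
    with np.errstate(invalid="ignore"):
        active = (speed > params.min_velocity_deg_s) | (
            np.abs(accel) > params.min_accel_deg_s2
        )
    sustain = max(1, int(round(params.min_sustain_ms / dt_ms)))

    x_deg = kin["x_deg"].to_numpy()
    y_deg = kin["y_deg"].to_numpy()
    x_px = samples["x_px"].to_numpy(dtype=float)
    y_px = samples["y_px"].to_numpy(dtype=float)
    n = len(t)

    padded = np.concatenate(([False], active, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    out: List[Saccade] = []
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < sustain:
            continue
        end_idx = min(stop, n - 1)  # landing sample (first quiet one)
        p_start = (x_deg[start], y_deg[start])
        p_end = (x_deg[end_idx], y_deg[end_idx])
        if np.isnan(p_start + p_end).any():
            continue
        amplitude = angular_distance(p_start, p_end)
        if amplitude <= params.min_deflection_deg:
            continue
        onset_ms = int(t[start])
        offset_ms = int(t[stop - 1]) + dt_ms
        if blinks and any(
            onset_ms < b.offset_ms and b.onset_ms < offset_ms for b in blinks
        ):
            continue
        out.append(
            Saccade(
                onset_ms=onset_ms,
                offset_ms=offset_ms,
                x_start_px=float(x_px[start]),
                y_start_px=float(y_px[start]),
                x_end_px=float(x_px[end_idx]),
                y_end_px=float(y_px[end_idx]),
                amplitude_deg=float(amplitude),
                peak_velocity_deg_s=float(np.nanmax(speed[start:stop])),
            )
        )
    return out


def _check_non_overlapping(intervals: List[Tuple[int, int]]) -> None:
    for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
        if b0 < a1:
            raise ValueError("overlapping input events passed to segment_fixations")


def segment_fixations(
    samples: pd.DataFrame,
    saccades: List[Saccade],
    blinks: List[Blink],
    trial_duration_ms: int,
) -> List[Fixation]:
    """Fixations are the maximal intervals not covered by saccades or blinks.

    The centroid is the mean sample position over the interval, and
    ``preceding_saccade_amplitude_deg`` is set from the immediately
    preceding saccade only when that saccade's offset abuts the fixation
    onset (a fixation right after a blink has no preceding amplitude).
    """
    occupied = sorted(
        [(s.onset_ms, s.offset_ms, "saccade", s) for s in saccades]
        + [(b.onset_ms, b.offset_ms, "blink", b) for b in blinks],
        key=lambda iv: iv[0],
    )
    _check_non_overlapping([(iv[0], iv[1]) for iv in occupied])

    t = samples["t_ms"].to_numpy()
    x = samples["x_px"].to_numpy(dtype=float)
    y = samples["y_px"].to_numpy(dtype=float)

    sacc_by_offset = {s.offset_ms: s for s in saccades}
    fixations: List[Fixation] = []
    cursor = 0
    gaps: List[Tuple[int, int]] = []
    for on, off, _, _ in occupied:
        if on > cursor:
            gaps.append((cursor, on))
        cursor = max(cursor, off)
    if cursor < trial_duration_ms:
        gaps.append((cursor, trial_duration_ms))

    for on, off in gaps:
        mask = (t >= on) & (t < off)
        if mask.any():
            cx = float(np.nanmean(x[mask]))
            cy = float(np.nanmean(y[mask]))
        else:
            cx = cy = float("nan")
        prev = sacc_by_offset.get(on)
        fixations.append(
            Fixation(
                onset_ms=int(on),
                offset_ms=int(off),
                x_px=cx,
                y_px=cy,
                preceding_saccade_amplitude_deg=(
                    float(prev.amplitude_deg) if prev is not None else None
                ),
            )
        )
    return fixations


def detect_trial(
    trial: TrialSamples,
    geometry: Optional[ScreenGeometry] = None,
    params: Optional[DetectionParams] = None,
    merge_gap_ms: int = 0,
) -> Trial:
    """Run blink, saccade and fixation segmentation on one trial."""
    geometry = geometry or ScreenGeometry()
    params = params or DetectionParams()
    blinks = detect_blinks(trial.samples, merge_gap_ms=merge_gap_ms)
    saccades = detect_saccades(trial.samples, geometry, params, blinks=blinks)
    fixations = segment_fixations(
        trial.samples, saccades, blinks, trial.meta.trial_duration_ms
    )
    return Trial(meta=trial.meta, fixations=fixations, saccades=saccades, blinks=blinks)


class SaccadeDetector(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: raw sample streams -> event table.

    Parameters
    ----------
    geometry : ScreenGeometry
    params : DetectionParams
    merge_gap_ms : int
        Blink merge gap passed to :func:`detect_blinks`.

    ``transform`` accepts the mapping returned by
    :func:`ambifocal.io_formats.read_samples` (or a single TrialSamples) and
    returns the canonical event DataFrame for all trials.
    """

    def __init__(
        self,
        geometry: Optional[ScreenGeometry] = None,
        params: Optional[DetectionParams] = None,
        merge_gap_ms: int = 0,
    ) -> None:
        self.geometry = geometry
        self.params = params
        self.merge_gap_ms = merge_gap_ms

    def fit(self, X=None, y=None) -> "SaccadeDetector":
        self.geometry_ = self.geometry or ScreenGeometry()
        self.params_ = self.params or DetectionParams()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "geometry_"):
            self.fit()
        if isinstance(X, TrialSamples):
            X = {(X.meta.participant_id, X.meta.trial_index): X}
        trials = [
            detect_trial(X[key], self.geometry_, self.params_, self.merge_gap_ms)
            for key in sorted(X)
        ]
        self.trials_ = trials
        return events_to_frame(trials)
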