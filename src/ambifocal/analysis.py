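"""Ambient/focal classification, early/late slicing, aggregation, pipeline.

A fixation is *ambient* when its preceding saccade was larger than 5 deg
(exploratory repositioning across the scene) and *focal* when the preceding
saccade was 5 deg or smaller (local examination); the first fixation of a
trial, or one following a blink, has no preceding saccade and stays
*unclassified*. Early viewing is the first 2 s of a trial, late viewing the
2-s window between 6 and 8 s (by which time all conditions have reached
their fixation-duration asymptote); events belong to an interval iff their
onset lies inside it.

``aggregate`` produces the tidy per-participant summary tables that a
standard stats package consumes (repeated-measures ANOVA etc. are
deliberately not computed here), and ``run_pipeline`` strings the whole
chain together: detect -> clean -> classify -> slice -> bin -> fit ->
aggregate.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import io_formats
from .cleaning import CleaningParams, CleanResult, clean
from .detection import DetectionParams, SaccadeDetector
from .geometry import ScreenGeometry
from .timecourse import AsymptoteFit, TimeCourse, bin_events, fit_asymptote, reach_time
from .types import CONDITIONS, TrialMeta

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalSpec",
    "attach_preceding_saccade",
    "classify_fixations",
    "AmbientFocalClassifier",
    "interval_slice",
    "aggregate",
    "grand_means",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

FACTOR_COLUMNS = {
    "condition": "condition",
    "scene_type": "scene_type",
    "interval": "interval",
    "fixation_type": "label",
}


@dataclass
class IntervalSpec:
    """Early/late analysis windows in ms, half-open."""

    early: Tuple[int, int] = (0, 2000)
    late: Tuple[int, int] = (6000, 8000)

    def __post_init__(self) -> None:
        for name in ("early", "late"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ValueError(f"IntervalSpec.{name} must be a non-empty interval")
        e, l = self.early, self.late
        if max(e[0], l[0]) < min(e[1], l[1]):
            raise ValueError("early and late intervals must be disjoint")


def attach_preceding_saccade(events: pd.DataFrame) -> pd.DataFrame:
    """Add ``preceding_saccade_amplitude_deg`` to fixation rows.

    A fixation's preceding saccade is the saccade (same trial) whose offset
    equals the fixation's onset; fixations without one (trial start, or
    following a blink) get NaN.
    """
    events = events.reset_index(drop=True).copy()
    amp = np.full(len(events), np.nan)
    for _, grp in events.groupby(["participant_id", "trial_index"], sort=False):
        sacc = grp[grp["event_kind"] == "saccade"]
        lut = dict(zip(sacc["offset_ms"], sacc["amplitude_deg"]))
        fix = grp[grp["event_kind"] == "fixation"]
        for idx, onset in zip(fix.index, fix["onset_ms"]):
            if onset in lut:
                amp[idx] = lut[onset]
    events["preceding_saccade_amplitude_deg"] = amp
    return events


class AmbientFocalClassifier(TransformerMixin, BaseEstimator):
    """Label fixations ambient/focal by preceding-saccade amplitude.

    amplitude > threshold_deg -> ambient; amplitude <= threshold_deg ->
    focal (ties go to focal: the published rule defines ">5" as ambient and
    "<5" as focal, leaving exact equality — a measure-zero case — to the
    implementation); no preceding saccade -> unclassified.
    """

    def __init__(self, threshold_deg: float = 5.0) -> None:
        self.threshold_deg = threshold_deg

    def fit(self, X=None, y=None) -> "AmbientFocalClassifier":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        events = X.reset_index(drop=True).copy()
        if "preceding_saccade_amplitude_deg" not in events.columns:
            events = attach_preceding_saccade(events)
        amp = events["preceding_saccade_amplitude_deg"].to_numpy(dtype=float)
        is_fix = (events["event_kind"] == "fixation").to_numpy()
        label = np.where(is_fix, "unclassified", "")
        with np.errstate(invalid="ignore"):
            label = np.where(is_fix & (amp > self.threshold_deg), "ambient", label)
            label = np.where(is_fix & (amp <= self.threshold_deg), "focal", label)
        events["label"] = label
        return events


def classify_fixations(events: pd.DataFrame, threshold_deg: float = 5.0) -> pd.DataFrame:
    """Thin wrapper over :class:`AmbientFocalClassifier`."""
    return AmbientFocalClassifier(threshold_deg=threshold_deg).fit().transform(events)


def interval_slice(events: pd.DataFrame, spec: IntervalSpec | None = None) -> pd.DataFrame:
    """Tag each event early/late/neither by whether its onset falls in the
    corresponding half-open window."""
    spec = spec or IntervalSpec()
    events = events.reset_index(drop=True).copy()
    onset = events["onset_ms"].to_numpy()
    tag = np.full(len(events), "neither", dtype=object)
    tag[(onset >= spec.early[0]) & (onset < spec.early[1])] = "early"
    tag[(onset >= spec.late[0]) & (onset < spec.late[1])] = "late"
    events["interval"] = tag
    return events


def aggregate(events: pd.DataFrame, factors: List[str] = ()) -> pd.DataFrame:
    """Per-participant cell means over the requested factor subset.

    Factors come from {"condition", "scene_type", "interval",
    "fixation_type"}. Every participant x cell combination appears, with
    ``n_events = 0`` and missing means for empty cells. Fixation-duration
    means are over fixation rows of the cell, saccade-amplitude means over
    saccade rows. Row order is deterministic (sorted).
    """
    for f in factors:
        if f not in FACTOR_COLUMNS:
            raise ValueError(f"unknown factor {f!r}")
        if FACTOR_COLUMNS[f] not in events.columns:
            raise ValueError(f"factor {f!r} requires column {FACTOR_COLUMNS[f]!r}")
    cols = [FACTOR_COLUMNS[f] for f in factors]

    participants = sorted(events["participant_id"].unique())
    levels = []
    for f, c in zip(factors, cols):
        if f == "interval":
            lv = [x for x in ("early", "late") if x in set(events[c])]
        elif f == "fixation_type":
            lv = [x for x in ("ambient", "focal") if x in set(events[c])]
        else:
            lv = sorted(x for x in events[c].dropna().unique() if x != "")
        levels.append(lv)

    fix = events[events["event_kind"] == "fixation"]
    sac = events[events["event_kind"] == "saccade"]
    # Interval/fixation-type cells only ever describe classified/sliced rows.
    if "interval" in factors:
        fix = fix[fix["interval"] != "neither"]
        sac = sac[sac["interval"] != "neither"]
    if "fixation_type" in factors:
        fix = fix[fix["label"].isin(["ambient", "focal"])]
        sac = sac.iloc[0:0]  # saccades carry no fixation-type factor

    rows = []
    fix_groups = fix.groupby(["participant_id", *cols], sort=False) if len(fix) else None
    sac_groups = sac.groupby(["participant_id", *cols], sort=False) if len(sac) else None
    fd_mean = fix_groups["duration_ms"].mean() if fix_groups is not None else pd.Series(dtype=float)
    fd_n = fix_groups.size() if fix_groups is not None else pd.Series(dtype=int)
    sa_mean = sac_groups["amplitude_deg"].mean() if sac_groups is not None else pd.Series(dtype=float)
    sa_n = sac_groups.size() if sac_groups is not None else pd.Series(dtype=int)

    for pid in participants:
        for combo in itertools.product(*levels) if levels else [()]:
            key = (pid, *combo) if combo else pid
            n_f = int(fd_n.get(key, 0))
            n_s = int(sa_n.get(key, 0))
            rows.append(
                (
                    pid,
                    *combo,
                    float(fd_mean.get(key, np.nan)),
                    float(sa_mean.get(key, np.nan)),
                    n_f + n_s,
                )
            )
    out = pd.DataFrame(rows, columns=["participant_id", *factors, "mean_fd_ms", "mean_sa_deg", "n_events"])
    return out.sort_values(["participant_id", *factors]).reset_index(drop=True)


def grand_means(summary: pd.DataFrame, factors: List[str] = ()) -> pd.DataFrame:
    """Unweighted mean of participant means per cell."""
    if not factors:
        return pd.DataFrame(
            {
                "mean_fd_ms": [summary["mean_fd_ms"].mean()],
                "mean_sa_deg": [summary["mean_sa_deg"].mean()],
                "n_participants": [summary["participant_id"].nunique()],
            }
        )
    g = summary.groupby(list(factors), sort=True)
    out = g[["mean_fd_ms", "mean_sa_deg"]].mean()
    out["n_participants"] = g["participant_id"].nunique()
    return out.reset_index()


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``samples`` (raw gaze; detection runs) or ``events`` (detection
    is skipped) must be provided. ``manifest`` supplies condition/scene
    metadata when events come without it.
    """

    samples: Union[None, str, Path, Dict] = None
    events: Union[None, str, Path, pd.DataFrame] = None
    manifest: Union[None, str, Path, List[TrialMeta], pd.DataFrame] = None
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    detection: DetectionParams = field(default_factory=DetectionParams)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    blink_merge_gap_ms: int = 0
    bin_ms: int = 500
    skip_bins_fd: int = 0
    skip_bins_sa: int = 2
    threshold_deg: float = 5.0
    intervals: IntervalSpec = field(default_factory=IntervalSpec)
    output_dir: Union[None, str, Path] = None


@dataclass
class PipelineResult:
    events: pd.DataFrame
    clean_result: CleanResult
    timecourses: Dict[str, TimeCourse]
    fits: Dict[str, AsymptoteFit]
    reach_times: Dict[str, Optional[float]]
    summaries: Dict[str, pd.DataFrame]


def _load_events(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.events is not None:
        if isinstance(cfg.events, pd.DataFrame):
            return cfg.events.copy()
        return io_formats.read_events(cfg.events)
    if cfg.samples is None:
        raise ValueError("PipelineConfig needs either samples or events")
    samples = cfg.samples
    if not isinstance(samples, dict):
        samples = io_formats.read_samples(samples, dialect="csv")
    detector = SaccadeDetector(
        geometry=cfg.geometry, params=cfg.detection, merge_gap_ms=cfg.blink_merge_gap_ms
    ).fit()
    events = detector.transform(samples)
    meta = {
        k: (v.meta.condition, v.meta.scene_type) for k, v in samples.items()
    }
    events["condition"] = [
        meta[(p, t)][0] for p, t in zip(events["participant_id"], events["trial_index"])
    ]
    events["scene_type"] = [
        meta[(p, t)][1] for p, t in zip(events["participant_id"], events["trial_index"])
    ]
    return events


def _merge_manifest(events: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    if "condition" in events.columns and "scene_type" in events.columns:
        return events
    if cfg.manifest is None:
        raise ValueError("events lack condition/scene_type and no manifest was given")
    man = cfg.manifest
    if isinstance(man, (str, Path)):
        man = io_formats.read_manifest(man)
    if isinstance(man, list):
        man = io_formats.manifest_frame(man)
    man = man[["participant_id", "trial_index", "condition", "scene_type"]]
    merged = events.merge(man, on=["participant_id", "trial_index"], how="left", validate="m:1")
    if merged["condition"].isna().any():
        missing = merged.loc[merged["condition"].isna(), ["participant_id", "trial_index"]]
        raise ValueError(f"manifest is missing trials: {missing.drop_duplicates().values.tolist()[:5]}")
    return merged


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run detect (optional) -> clean -> classify -> slice -> bin -> fit ->
    aggregate, optionally writing every artefact to ``config.output_dir``.

    Fully deterministic for a given input. Stage failures are re-raised
    with the stage name prepended.
    """
    stages = []

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages.append((name, time.perf_counter() - t0))
        logger.info("stage %s: %.2fs", name, stages[-1][1])
        return out

    events = run_stage("load/detect", lambda: _merge_manifest(_load_events(config), config))
    clean_result = run_stage("clean", lambda: clean(events, config.cleaning))
    cleaned = clean_result.events
    cleaned = run_stage("classify", lambda: classify_fixations(cleaned, config.threshold_deg))
    cleaned = run_stage("slice", lambda: interval_slice(cleaned, config.intervals))

    timecourses: Dict[str, TimeCourse] = {}
    fits: Dict[str, AsymptoteFit] = {}
    reach_times: Dict[str, Optional[float]] = {}

    def fit_all() -> None:
        groups = [("pooled", cleaned)] + [
            (cond, cleaned[cleaned["condition"] == cond]) for cond in CONDITIONS
        ]
        for name, grp in groups:
            if grp.empty:
                continue
            for measure, skip in (
                ("fixation_duration_ms", config.skip_bins_fd),
                ("saccade_amplitude_deg", config.skip_bins_sa),
            ):
                key = f"{measure}/{name}"
                tc = bin_events(grp, measure=measure, bin_ms=config.bin_ms)
                timecourses[key] = tc
                fit = fit_asymptote(tc, skip_bins=skip)
                fits[key] = fit
                reach_times[key] = reach_time(fit, tc) if fit.converged else None

    run_stage("bin/fit", fit_all)

    summaries: Dict[str, pd.DataFrame] = {}

    def summarize() -> None:
        summaries["condition"] = aggregate(cleaned, ["condition"])
        summaries["condition_scene"] = aggregate(cleaned, ["condition", "scene_type"])
        summaries["condition_interval"] = aggregate(cleaned, ["condition", "interval"])
        summaries["condition_fixation_type"] = aggregate(
            cleaned, ["condition", "fixation_type"]
        )

    run_stage("aggregate", summarize)

    result = PipelineResult(
        events=cleaned,
        clean_result=clean_result,
        timecourses=timecourses,
        fits=fits,
        reach_times=reach_times,
        summaries=summaries,
    )
    if config.output_dir is not None:
        run_stage("write", lambda: _write_outputs(result, config))
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_events(result.events, str(out / "clean_events.csv"))
    with open(out / "cleaning_report.json", "w", encoding="utf-8") as fh:
        json.dump(result.clean_result.report.to_dict(), fh, indent=2, sort_keys=True)
    tc_frames = []
    for key, tc in sorted(result.timecourses.items()):
        measure, name = key.split("/")
        tc_frames.append(tc.table.assign(measure=measure, group=name))
    pd.concat(tc_frames, ignore_index=True).to_csv(out / "timecourses.csv", index=False)
    fits_obj = {}
    for key, fit in sorted(result.fits.items()):
        d = fit.to_dict()
        d["reach_time_s"] = result.reach_times.get(key)
        fits_obj[key] = d
    with open(out / "fits.json", "w", encoding="utf-8") as fh:
        json.dump(fits_obj, fh, indent=2, sort_keys=True)
    for name, summary in sorted(result.summaries.items()):
        summary.to_csv(out / f"summary_{name}.csv", index=False)
    params = {
        "detection": vars(config.detection),
        "cleaning": vars(config.cleaning),
        "bin_ms": config.bin_ms,
        "skip_bins_fd": config.skip_bins_fd,
        "skip_bins_sa": config.skip_bins_sa,
        "threshold_deg": config.threshold_deg,
        "intervals": {"early": list(config.intervals.early), "late": list(config.intervals.late)},
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
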