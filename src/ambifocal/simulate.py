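"""Synthetic scanpath generator with ground truth.

The generator emulates the study design: 42 participants x 90 trials of
20-s free viewing (30 trials per visual condition, 15 natural + 15 urban
scenes within each condition), recorded at 1000 Hz. Each trial is an
alternating fixation-saccade renewal process whose moments follow the same
time-course law the analysis fits:

* fixation durations are Gamma(shape kappa) with mean
  ``b_fd * exp(a_fd / t)``;
* saccade amplitudes are lognormal (log-sd ``sa_sigma_log``) with mean
  ``b_sa * exp(a_sa / t)``, restricted to the mask-consistent range for the
  trial's condition (<= 5 deg from gaze under the central window, > 5 deg
  under the peripheral scotoma, unconstrained in control) and the lognormal
  location solved numerically so the *conditional* mean equals the curve —
  the condition curves describe realized means, and naive truncation would
  bias them;
* the curve clock is evaluated at the end of the 500-ms bin containing the
  event onset, the same lattice the analysis bins on, so per-bin expected
  means equal the curve at the bin label exactly (this is what makes
  parameter-recovery experiments well-posed);
* blinks arrive as a Poisson process; arrivals landing inside a fixation
  zero the pupil, mask gaze position, and split the fixation, so the
  realized event list still partitions the trial;
* saccades are rendered with a raised-cosine velocity profile (duration
  ~ 21 + 2.2*A ms, capped so the peak velocity clears the 30 deg/s
  detection threshold for any amplitude >= ~0.3 deg) and Gaussian
  positional noise (sd ``noise_sd_deg``) is added during fixations.

Condition defaults take the published per-condition asymptotes (fixation
durations 283.5 / 311.4 / 321.2 ms and saccade amplitudes 3.5 / 8.1 /
5.4 deg for central / peripheral / control) with acceleration rates chosen
to land reach times near the published 3.5-6 s range.

``simulate_dataset(..., render_samples=False)`` produces the ground-truth
event tables alone, which is orders of magnitude faster than rendering
1000 Hz sample streams and is the natural input for event-level
parameter-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .geometry import ScreenGeometry, deg_to_px
from .io_formats import TrialSamples, manifest_frame
from .types import CONDITIONS, EVENT_COLUMNS, TrialMeta

__all__ = [
    "ConditionParams",
    "SimulationConfig",
    "simulate_trial",
    "simulate_dataset",
    "truth_compare",
]


@dataclass
class ConditionParams:
    """Time-course curve parameters for one visual condition."""

    b_fd: float  # fixation-duration asymptote, ms
    a_fd: float  # fixation-duration acceleration rate, s (negative: rising)
    b_sa: float  # saccade-amplitude asymptote, deg
    a_sa: float  # saccade-amplitude acceleration rate, s (positive: falling)


DEFAULT_CONDITIONS: Dict[str, ConditionParams] = {
    "central": ConditionParams(283.5, -0.15, 3.5, 0.3),
    "peripheral": ConditionParams(311.4, -0.25, 8.1, 0.4),
    "control": ConditionParams(321.2, -0.23, 5.4, 0.4),
}


@dataclass
class SimulationConfig:
    conditions: Dict[str, ConditionParams] = field(
        default_factory=lambda: {k: replace(v) for k, v in DEFAULT_CONDITIONS.items()}
    )
    fd_shape: float = 6.0  # gamma shape for fixation durations
    sa_sigma_log: float = 0.35  # lognormal log-sd for saccade amplitudes
    noise_sd_deg: float = 0.03  # gaussian positional noise during fixations
    blink_rate_per_s: float = 0.12
    blink_dur_mean_ms: float = 150.0
    n_participants: int = 42
    trials_per_condition: int = 30
    trial_ms: int = 20000
    sample_rate_hz: int = 1000
    mask_radius_deg: float = 5.0
    bin_ms: int = 500
    seed: int = 0
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        for name in (
            "fd_shape", "sa_sigma_log", "blink_dur_mean_ms",
            "n_participants", "trials_per_condition", "trial_ms", "sample_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimulationConfig.{name} must be strictly positive")
        if self.noise_sd_deg < 0 or self.blink_rate_per_s < 0:
            raise ValueError("noise_sd_deg and blink_rate_per_s must be >= 0")


def _bin_clock_s(t_ms: float, bin_ms: int) -> float:
    """End time (s) of the bin containing t; the generator's curve clock."""
    return (math.floor(t_ms / bin_ms) + 1) * bin_ms / 1000.0


def saccade_duration_ms(amplitude_deg: float) -> int:
    """Main-sequence-style duration: ~21 + 2.2*A ms, shortened for small
    amplitudes so the raised-cosine peak velocity (2A/D) clears 30 deg/s
    whenever A >= ~0.3 deg."""
    d = min(21.0 + 2.2 * amplitude_deg, 57.0 * amplitude_deg)
    return max(4, int(round(d)))


class _TruncatedLognormalSampler:
    """Lognormal sampler with a prescribed *conditional* mean on (lo, hi).

    Solves for the log-location mu such that E[X | lo < X < hi] equals the
    target mean at fixed log-sd sigma, then samples by inverse CDF on the
    truncated range. Solutions are cached per (target, lo, hi)."""

    def __init__(self, sigma: float) -> None:
        self.sigma = sigma
        self._cache: Dict[Tuple[float, float, float], Tuple[float, float, float]] = {}

    def _conditional_mean(self, mu: float, lo: float, hi: float) -> float:
        s = self.sigma
        alpha = (math.log(lo) - mu) / s if lo > 0 else -np.inf
        beta = (math.log(hi) - mu) / s if np.isfinite(hi) else np.inf
        z = ndtr(beta) - ndtr(alpha)
        if z <= 0:
            return hi if np.isfinite(hi) else np.inf
        num = ndtr(beta - s) - ndtr(alpha - s)
        return math.exp(mu + s * s / 2.0) * num / z

    def _solve(self, target: float, lo: float, hi: float) -> Tuple[float, float, float]:
        key = (round(target, 9), lo, hi)
        if key in self._cache:
            return self._cache[key]
        s = self.sigma
        # Bracket mu; clamp infeasible targets to the achievable extreme.
        mu_lo = math.log(max(lo, 1e-3)) - 8 * s if lo > 0 else math.log(target) - 8 * s
        mu_hi = (math.log(hi) + 3 * s) if np.isfinite(hi) else math.log(target) + 8 * s
        f_lo = self._conditional_mean(mu_lo, lo, hi) - target
        f_hi = self._conditional_mean(mu_hi, lo, hi) - target
        if f_lo >= 0:
            mu = mu_lo
        elif f_hi <= 0:
            mu = mu_hi
        else:
            mu = brentq(
                lambda m: self._conditional_mean(m, lo, hi) - target, mu_lo, mu_hi,
                xtol=1e-10,
            )
        p_lo = float(ndtr((math.log(lo) - mu) / s)) if lo > 0 else 0.0
        p_hi = float(ndtr((math.log(hi) - mu) / s)) if np.isfinite(hi) else 1.0
        out = (mu, p_lo, p_hi)
        self._cache[key] = out
        return out

    def sample(self, target: float, lo: float, hi: float, rng: np.random.Generator) -> float:
        mu, p_lo, p_hi = self._solve(target, lo, hi)
        u = p_lo + rng.random() * (p_hi - p_lo)
        u = min(max(u, 1e-12), 1 - 1e-12)
        return math.exp(mu + self.sigma * ndtri(u))


def _amplitude_bounds(condition: str, cfg: SimulationConfig) -> Tuple[float, float]:
    if condition == "central":
        return (0.0, cfg.mask_radius_deg)
    if condition == "peripheral":
        return (cfg.mask_radius_deg, np.inf)
    return (0.0, np.inf)


def _draw_endpoint(
    gaze: Tuple[float, float],
    amp: float,
    geo: ScreenGeometry,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> Tuple[Tuple[float, float], float]:
    """Pick a uniform-direction endpoint at the drawn amplitude, keeping it
    on screen; after ``max_tries`` rejections the endpoint is clamped onto
    the screen and the amplitude recomputed (rare fallback)."""
    hw, hh = geo.half_width_deg, geo.half_height_deg
    # Cap at the farthest reachable corner so a direction always exists.
    corner = max(
        math.hypot(sx * hw - gaze[0], sy * hh - gaze[1])
        for sx in (-1, 1) for sy in (-1, 1)
    )
    amp = min(amp, corner)
    for _ in range(max_tries):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        end = (gaze[0] + amp * math.cos(theta), gaze[1] + amp * math.sin(theta))
        if abs(end[0]) <= hw and abs(end[1]) <= hh:
            return end, amp
    end = (min(max(end[0], -hw), hw), min(max(end[1], -hh), hh))
    return end, math.hypot(end[0] - gaze[0], end[1] - gaze[1])


@dataclass
class _TruthEvent:
    kind: str
    onset_ms: int
    offset_ms: int
    start: Tuple[float, float] = (math.nan, math.nan)  # deg
    end: Tuple[float, float] = (math.nan, math.nan)
    amplitude_deg: float = math.nan
    preceding_amp: Optional[float] = None


def _simulate_trial_events(
    cfg: SimulationConfig, condition: str, rng: np.random.Generator
) -> List[_TruthEvent]:
    cp = cfg.conditions[condition]
    lo, hi = _amplitude_bounds(condition, cfg)
    sampler = _amp_sampler(cfg)
    geo = cfg.geometry
    gaze = (0.0, 0.0)
    t = 0
    last_amp: Optional[float] = None
    out: List[_TruthEvent] = []

    while t < cfg.trial_ms:
        # --- fixation ---
        t_clock = _bin_clock_s(t, cfg.bin_ms)
        mean_fd = cp.b_fd * math.exp(cp.a_fd / t_clock)
        dur = max(1, int(round(rng.gamma(cfg.fd_shape, mean_fd / cfg.fd_shape))))
        fix_on, fix_off = t, min(t + dur, cfg.trial_ms)

        blinks = _draw_blinks(cfg, fix_on, fix_off, rng)
        cursor = fix_on
        first = True
        for b_on, b_off in blinks:
            if b_on > cursor:
                out.append(
                    _TruthEvent("fixation", cursor, b_on, gaze, gaze,
                                preceding_amp=last_amp if first else None)
                )
                first = False
            out.append(_TruthEvent("blink", b_on, b_off))
            cursor = b_off
        if cursor < fix_off:
            out.append(
                _TruthEvent("fixation", cursor, fix_off, gaze, gaze,
                            preceding_amp=last_amp if first else None)
            )
        t = fix_on + dur
        if t >= cfg.trial_ms:
            break

        # --- saccade ---
        t_clock = _bin_clock_s(t, cfg.bin_ms)
        target_mean = cp.b_sa * math.exp(cp.a_sa / t_clock)
        amp = sampler.sample(target_mean, lo, hi, rng)
        end, amp = _draw_endpoint(gaze, amp, geo, rng)
        dur = saccade_duration_ms(amp)
        sac_on, sac_off = t, min(t + dur, cfg.trial_ms)
        if sac_off > sac_on:
            out.append(_TruthEvent("saccade", sac_on, sac_off, gaze, end, amplitude_deg=amp))
        gaze = end
        last_amp = amp
        t = sac_on + dur
    return out


def _amp_sampler(cfg: SimulationConfig) -> _TruncatedLognormalSampler:
    # One cached sampler per config (cache key includes the targets).
    sampler = getattr(cfg, "_sampler", None)
    if sampler is None or sampler.sigma != cfg.sa_sigma_log:
        sampler = _TruncatedLognormalSampler(cfg.sa_sigma_log)
        object.__setattr__(cfg, "_sampler", sampler)
    return sampler


def _draw_blinks(
    cfg: SimulationConfig, fix_on: int, fix_off: int, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    """Poisson blink arrivals realized inside one fixation, clipped to it."""
    if cfg.blink_rate_per_s <= 0:
        return []
    span_s = (fix_off - fix_on) / 1000.0
    n = rng.poisson(cfg.blink_rate_per_s * span_s)
    if n == 0:
        return []
    onsets = np.sort(rng.uniform(fix_on, fix_off, size=n))
    durs = rng.exponential(cfg.blink_dur_mean_ms, size=n)
    merged: List[Tuple[int, int]] = []
    for on, d in zip(onsets, durs):
        on_i = int(round(on))
        off_i = min(int(round(on + max(d, 1.0))), fix_off)
        if off_i - on_i < 1:
            continue
        # Swallow sub-millisecond fixation fragments at the edges.
        if fix_off - off_i < 1:
            off_i = fix_off
        if on_i - fix_on < 1:
            on_i = fix_on
        if merged and on_i <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], off_i))
        else:
            merged.append((on_i, off_i))
    return [iv for iv in merged if iv[1] > iv[0]]


def _truth_frame(
    events: List[_TruthEvent], meta: TrialMeta, geo: Optional[ScreenGeometry] = None
) -> pd.DataFrame:
    geo = geo or ScreenGeometry()
    rows = []
    for ev in events:
        xs, ys = deg_to_px(*ev.start, geo) if not math.isnan(ev.start[0]) else (math.nan, math.nan)
        xe, ye = deg_to_px(*ev.end, geo) if not math.isnan(ev.end[0]) else (math.nan, math.nan)
        rows.append(
            (
                meta.participant_id, meta.trial_index, ev.kind,
                ev.onset_ms, ev.offset_ms, ev.offset_ms - ev.onset_ms,
                xs, ys, xe, ye, ev.amplitude_deg,
                math.nan if ev.preceding_amp is None else ev.preceding_amp,
                meta.condition, meta.scene_type,
            )
        )
    return pd.DataFrame(
        rows,
        columns=EVENT_COLUMNS + ["preceding_saccade_amplitude_deg", "condition", "scene_type"],
    )


def _render_trial(
    cfg: SimulationConfig, events: List[_TruthEvent], meta: TrialMeta,
    rng: np.random.Generator,
) -> TrialSamples:
    """Render a ground-truth event list into a 1000 Hz sample stream."""
    geo = cfg.geometry
    n = cfg.trial_ms  # 1 sample per ms
    x = np.empty(n)
    y = np.empty(n)
    pupil = np.full(n, 1000.0)
    sx = geo.half_width_deg / (geo.width_px / 2.0)
    sy = geo.half_height_deg / (geo.height_px / 2.0)

    for ev in events:
        on, off = ev.onset_ms, min(ev.offset_ms, n)
        if off <= on:
            continue
        if ev.kind == "fixation":
            m = off - on
            x[on:off] = ev.start[0] + rng.normal(0.0, cfg.noise_sd_deg, size=m)
            y[on:off] = ev.start[1] + rng.normal(0.0, cfg.noise_sd_deg, size=m)
        elif ev.kind == "saccade":
            D = ev.offset_ms - ev.onset_ms
            tau = np.arange(0, off - on)
            # Raised-cosine velocity => smooth sigmoidal displacement.
            frac = tau / D - np.sin(2 * math.pi * tau / D) / (2 * math.pi)
            x[on:off] = ev.start[0] + (ev.end[0] - ev.start[0]) * frac
            y[on:off] = ev.start[1] + (ev.end[1] - ev.start[1]) * frac
        else:  # blink
            x[on:off] = np.nan
            y[on:off] = np.nan
            pupil[on:off] = 0.0

    x_px = x / sx + geo.width_px / 2.0
    y_px = y / sy + geo.height_px / 2.0
    samples = pd.DataFrame(
        {"t_ms": np.arange(n, dtype=np.int64), "x_px": x_px, "y_px": y_px, "pupil": pupil}
    )
    return TrialSamples(meta=meta, samples=samples)


def simulate_trial(
    cfg: SimulationConfig,
    condition: str,
    seed: Optional[int] = None,
    meta: Optional[TrialMeta] = None,
    render: bool = True,
) -> Tuple[Optional[TrialSamples], pd.DataFrame]:
    """Simulate one trial; returns (samples, ground-truth event table).

    ``samples`` is None when ``render=False``. The event stream for a given
    seed is identical whether or not samples are rendered (rendering uses a
    separate child generator).
    """
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    meta = meta or TrialMeta(
        participant_id="sim", trial_index=1, condition=condition,
        scene_type="natural", trial_duration_ms=cfg.trial_ms,
    )
    ss = np.random.SeedSequence([cfg.seed if seed is None else seed])
    ev_ss, render_ss = ss.spawn(2)
    events = _simulate_trial_events(cfg, condition, np.random.default_rng(ev_ss))
    truth = _truth_frame(events, meta, cfg.geometry)
    samples = (
        _render_trial(cfg, events, meta, np.random.default_rng(render_ss)) if render else None
    )
    return samples, truth


def _make_manifest(cfg: SimulationConfig, rng: np.random.Generator) -> List[TrialMeta]:
    metas: List[TrialMeta] = []
    half = cfg.trials_per_condition // 2
    n_nat = {c: 0 for c in cfg.conditions}
    n_urb = {c: 0 for c in cfg.conditions}
    for p in range(cfg.n_participants):
        pid = f"p{p + 1:02d}"
        labels = []
        scene_no = 0
        for cond in sorted(cfg.conditions):
            for i in range(cfg.trials_per_condition):
                scene = "natural" if i < half else "urban"
                labels.append((cond, scene))
        order = rng.permutation(len(labels))
        for ti, j in enumerate(order, start=1):
            cond, scene = labels[j]
            scene_no += 1
            metas.append(
                TrialMeta(
                    participant_id=pid, trial_index=ti, condition=cond,
                    scene_type=scene, scene_id=f"scene{scene_no:03d}",
                    trial_duration_ms=cfg.trial_ms,
                )
            )
    return metas


def simulate_dataset(
    cfg: SimulationConfig, render_samples: bool = True
) -> Tuple[Optional[Dict], pd.DataFrame, pd.DataFrame]:
    """Simulate the full design.

    Returns (samples map or None, ground-truth event table, manifest frame).
    Per-trial child seeds are derived deterministically from
    ``(cfg.seed, participant, trial)``, so any subset of trials reproduces
    identically regardless of iteration order.
    """
    man_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11CE]))
    metas = _make_manifest(cfg, man_rng)
    samples_map: Dict = {} if render_samples else None
    truth_frames: List[pd.DataFrame] = []
    for meta in metas:
        p_idx = int(meta.participant_id[1:])
        ss = np.random.SeedSequence([cfg.seed, p_idx, meta.trial_index])
        ev_ss, render_ss = ss.spawn(2)
        events = _simulate_trial_events(
            cfg, meta.condition, np.random.default_rng(ev_ss)
        )
        truth_frames.append(_truth_frame(events, meta, cfg.geometry))
        if render_samples:
            samples_map[(meta.participant_id, meta.trial_index)] = _render_trial(
                cfg, events, meta, np.random.default_rng(render_ss)
            )
    truth = pd.concat(truth_frames, ignore_index=True)
    return samples_map, truth, manifest_frame(metas)


def truth_compare(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    tol_ms: int = 4,
    tol_deg: float = 0.1,
) -> Dict:
    """Greedy onset-ordered matching of detected events against truth.

    Events match when they share (trial, kind) and their onsets differ by
    at most ``tol_ms``. Returns per-kind hit/miss/spurious counts plus
    onset/offset error quantiles and, for saccades, amplitude error
    quantiles; ``amplitude_within_tol`` is the fraction of matched saccades
    with |amplitude error| <= tol_deg.
    """
    d_keys = set(zip(detected["participant_id"], detected["trial_index"]))
    t_keys = set(zip(truth["participant_id"], truth["trial_index"]))
    if d_keys != t_keys:
        raise ValueError("detected and truth cover different trial sets")

    report: Dict = {}
    for kind in ("fixation", "saccade", "blink"):
        hits = 0
        misses = 0
        spurious = 0
        onset_err: List[float] = []
        offset_err: List[float] = []
        amp_err: List[float] = []
        for key in sorted(t_keys):
            dt = detected[
                (detected["participant_id"] == key[0])
                & (detected["trial_index"] == key[1])
                & (detected["event_kind"] == kind)
            ].sort_values("onset_ms")
            tt = truth[
                (truth["participant_id"] == key[0])
                & (truth["trial_index"] == key[1])
                & (truth["event_kind"] == kind)
            ].sort_values("onset_ms")
            di, ti = 0, 0
            d_on = dt["onset_ms"].to_numpy()
            d_off = dt["offset_ms"].to_numpy()
            d_amp = dt["amplitude_deg"].to_numpy()
            t_on = tt["onset_ms"].to_numpy()
            t_off = tt["offset_ms"].to_numpy()
            t_amp = tt["amplitude_deg"].to_numpy()
            while di < len(d_on) and ti < len(t_on):
                diff = d_on[di] - t_on[ti]
                if abs(diff) <= tol_ms:
                    hits += 1
                    onset_err.append(abs(float(diff)))
                    offset_err.append(abs(float(d_off[di] - t_off[ti])))
                    if kind == "saccade":
                        amp_err.append(abs(float(d_amp[di] - t_amp[ti])))
                    di += 1
                    ti += 1
                elif diff < 0:
                    spurious += 1
                    di += 1
                else:
                    misses += 1
                    ti += 1
            spurious += len(d_on) - di
            misses += len(t_on) - ti

        def q(vals: List[float]) -> Dict[str, float]:
            if not vals:
                return {"p50": math.nan, "p95": math.nan, "max": math.nan}
            arr = np.asarray(vals)
            return {
                "p50": float(np.quantile(arr, 0.5)),
                "p95": float(np.quantile(arr, 0.95)),
                "max": float(arr.max()),
            }

        entry = {
            "hits": hits,
            "misses": misses,
            "spurious": spurious,
            "hit_rate": hits / (hits + misses) if hits + misses else math.nan,
            "onset_error_ms": q(onset_err),
            "offset_error_ms": q(offset_err),
        }
        if kind == "saccade":
            entry["amplitude_error_deg"] = q(amp_err)
            entry["amplitude_within_tol"] = (
                float(np.mean(np.asarray(amp_err) <= tol_deg)) if amp_err else math.nan
            )
        report[kind] = entry
    return report
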