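"""500-ms time-course binning and the nonlinear asymptote model.

Scene-viewing trials are parcelled into 500-ms bins by event onset, bin
means are computed per participant and then averaged across participants
with a t-distribution 95% CI, and the bin means are fit with the
two-parameter exponential-approach model

    y(t) = b * exp(a / t)

where ``b`` is the asymptote (the value approached as t -> infinity) and
``a`` is the acceleration rate in seconds: a < 0 gives a curve rising
toward b (fixation durations), a > 0 a curve falling toward b (saccade
amplitudes). Bins are labelled by their END time, t_k = k * 0.5 s, which
matches the convention of calling bin three "1.5 seconds". For saccade
amplitudes the first two bins are excluded from the regression
(``skip_bins=2``) because amplitudes first rise to a peak at bin three
before declining toward asymptote.

The time-to-asymptote is the t of the first bin (after skipping) whose 95%
CI contains the fitted asymptote b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TimeCourse",
    "AsymptoteFit",
    "asymptote_curve",
    "bin_events",
    "AsymptoteModel",
    "fit_asymptote",
    "reach_time",
    "predict",
]

MEASURES = {
    "fixation_duration_ms": ("fixation", "duration_ms"),
    "saccade_amplitude_deg": ("saccade", "amplitude_deg"),
}


@dataclass
class TimeCourse:
    """Binned means with CIs.

    ``table`` columns: bin (1-based), t_s (= bin * bin_ms / 1000, the bin
    end time), mean, ci_lo, ci_hi, n_participants, low_n (flag for bins
    with fewer than two participants, whose CI is undefined).
    """

    measure: str
    bin_ms: int
    table: pd.DataFrame


def asymptote_curve(t_s, b: float, a: float):
    """The model curve b * exp(a / t)."""
    return b * np.exp(a / np.asarray(t_s, dtype=float))


def bin_events(
    events: pd.DataFrame,
    measure: str = "fixation_duration_ms",
    bin_ms: int = 500,
    ci: float = 0.95,
) -> TimeCourse:
    """Bin events by onset into ``bin_ms`` intervals and aggregate.

    An event with onset in ``[(k-1)*bin_ms, k*bin_ms)`` belongs to bin k.
    Participant means are computed first; the grand mean and CI per bin are
    across participants (t distribution, n-1 df). Raises if there are no
    events of the measure's kind.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    kind, value_col = MEASURES[measure]
    sub = events[events["event_kind"] == kind]
    sub = sub[np.isfinite(sub[value_col].to_numpy(dtype=float))]
    if sub.empty:
        raise ValueError(f"no {kind} events to bin for measure {measure}")
    bins = sub["onset_ms"].to_numpy() // bin_ms + 1
    per_part = (
        sub.assign(bin=bins)
        .groupby(["bin", "participant_id"], sort=True)[value_col]
        .mean()
    )
    rows = []
    alpha = 1.0 - ci
    for k, vals in per_part.groupby(level="bin"):
        v = vals.to_numpy(dtype=float)
        n = len(v)
        m = float(np.mean(v))
        if n >= 2:
            half = float(stats.t.ppf(1 - alpha / 2, n - 1) * np.std(v, ddof=1) / math.sqrt(n))
        else:
            half = math.nan
        rows.append((int(k), k * bin_ms / 1000.0, m, m - half, m + half, n, n < 2))
    table = pd.DataFrame(
        rows, columns=["bin", "t_s", "mean", "ci_lo", "ci_hi", "n_participants", "low_n"]
    ).sort_values("bin").reset_index(drop=True)
    return TimeCourse(measure=measure, bin_ms=bin_ms, table=table)


@dataclass
class AsymptoteFit:
    """Fitted parameters of y = b * exp(a / t)."""

    b: float
    a: float
    b_ci: tuple
    skip_bins: int
    residual_sse: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "b": self.b,
            "a": self.a,
            "b_ci": list(self.b_ci),
            "skip_bins": self.skip_bins,
            "residual_sse": self.residual_sse,
            "converged": self.converged,
        }


class AsymptoteModel(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares estimator for y = b * exp(a / t).

    Initialisation: b0 = mean of the last three usable bin means, a0 = the
    slope of an ordinary regression of log(y) on 1/t (exact on noiseless
    data, since log y = log b + a/t). Convergence tolerance 1e-10 on the
    parameters. The fit is invariant to the ordering of the input points.

    Fitted attributes: ``b_``, ``a_``, ``b_ci_`` (95%, t-based from the
    estimator covariance), ``residual_sse_``, ``converged_``.
    """

    def __init__(self, skip_bins: int = 0, tol: float = 1e-10, ci: float = 0.95) -> None:
        self.skip_bins = skip_bins
        self.tol = tol
        self.ci = ci

    def fit(self, t_s, y) -> "AsymptoteModel":
        t = np.asarray(t_s, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise ValueError("t and y must have the same length")
        order = np.argsort(t)
        t, y = t[order], y[order]
        if self.skip_bins:
            t, y = t[self.skip_bins:], y[self.skip_bins:]
        ok = np.isfinite(t) & np.isfinite(y) & (t > 0) & (y > 0)
        t, y = t[ok], y[ok]
        if len(t) < 4:
            raise ValueError("fit requires at least 4 usable bins after skipping")

        b0 = float(np.mean(y[-3:]))
        a0 = float(np.polyfit(1.0 / t, np.log(y), 1)[0])
        self.n_points_ = len(t)
        try:
            popt, pcov = optimize.curve_fit(
                asymptote_curve, t, y, p0=[b0, a0],
                xtol=self.tol, ftol=self.tol, gtol=self.tol, maxfev=20000,
            )
            self.converged_ = bool(np.all(np.isfinite(popt)))
        except RuntimeError:
            popt = np.array([b0, a0])
            pcov = np.full((2, 2), np.nan)
            self.converged_ = False
        self.b_, self.a_ = float(popt[0]), float(popt[1])
        resid = y - asymptote_curve(t, self.b_, self.a_)
        self.residual_sse_ = float(np.sum(resid**2))
        df = max(len(t) - 2, 1)
        se_b = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.nan
        half = stats.t.ppf(1 - (1 - self.ci) / 2, df) * se_b
        self.b_ci_ = (self.b_ - half, self.b_ + half)
        return self

    def predict(self, t_s):
        t = np.asarray(t_s, dtype=float)
        if np.any(t <= 0):
            raise ValueError("the model is defined for t > 0 only")
        return asymptote_curve(t, self.b_, self.a_)

    def as_fit(self) -> AsymptoteFit:
        return AsymptoteFit(
            b=self.b_,
            a=self.a_,
            b_ci=self.b_ci_,
            skip_bins=self.skip_bins,
            residual_sse=self.residual_sse_,
            converged=self.converged_,
        )


def fit_asymptote(tc: TimeCourse, skip_bins: int = 0) -> AsymptoteFit:
    """Fit the asymptote model to a time course's bin means."""
    model = AsymptoteModel(skip_bins=skip_bins)
    model.fit(tc.table["t_s"].to_numpy(), tc.table["mean"].to_numpy())
    return model.as_fit()


def reach_time(fit: AsymptoteFit, tc: TimeCourse) -> Optional[float]:
    """Time at which the measure reaches asymptote.

    The first bin (after ``fit.skip_bins``) whose 95% CI contains the
    fitted asymptote b; ``None`` when no bin qualifies. Requires a
    converged fit.
    """
    if not fit.converged:
        raise ValueError("reach_time requires a converged fit")
    table = tc.table.sort_values("bin")
    for row in table.itertuples(index=False):
        if row.bin <= fit.skip_bins or row.low_n:
            continue
        if row.ci_lo <= fit.b <= row.ci_hi:
            return float(row.t_s)
    return None


def predict(fit: AsymptoteFit, t_s):
    """Evaluate the fitted curve at time(s) t_s (seconds, > 0)."""
    t = np.asarray(t_s, dtype=float)
    if np.any(t <= 0):
        raise ValueError("predict requires t_s > 0")
    out = asymptote_curve(t, fit.b, fit.a)
    return float(out) if np.ndim(t_s) == 0 else out
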