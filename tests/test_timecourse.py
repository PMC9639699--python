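import math

import numpy as np
import pandas as pd
import pytest

from ambifocal.timecourse import (
    AsymptoteFit,
    AsymptoteModel,
    TimeCourse,
    asymptote_curve,
    bin_events,
    fit_asymptote,
    predict,
    reach_time,
)

from conftest import make_event, make_events


def synthetic_timecourse(b, a, n_bins=12, half_width=5.0):
    t = np.arange(1, n_bins + 1) * 0.5
    mean = asymptote_curve(t, b, a)
    table = pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "t_s": t,
            "mean": mean,
            "ci_lo": mean - half_width,
            "ci_hi": mean + half_width,
            "n_participants": 10,
            "low_n": False,
        }
    )
    return TimeCourse(measure="fixation_duration_ms", bin_ms=500, table=table)


# ----------------------------------------------------------------- binning


@pytest.mark.parametrize("onset, expected_bin", [(0, 1), (499, 1), (1499, 3), (1500, 4)])
def test_half_open_bin_edges(onset, expected_bin):
    ev = make_events([make_event(onset=onset, offset=onset + 300)])
    tc = bin_events(ev, "fixation_duration_ms")
    assert list(tc.table["bin"]) == [expected_bin]


def test_bin_three_is_labelled_1500ms():
    ev = make_events([make_event(onset=1200, offset=1500)])
    tc = bin_events(ev, "fixation_duration_ms")
    assert tc.table["t_s"].iloc[0] == pytest.approx(1.5)


def test_single_participant_bin_flagged_with_undefined_ci():
    ev = make_events([make_event(onset=100, offset=400)])
    tc = bin_events(ev, "fixation_duration_ms")
    row = tc.table.iloc[0]
    assert row["mean"] == 300 and row["low_n"]
    assert math.isnan(row["ci_lo"])


def test_participant_means_before_grand_mean():
    # p01 contributes {200, 300} -> 250; p02 contributes {400} -> 400
    ev = make_events(
        [
            make_event(pid="p01", onset=0, offset=200),
            make_event(pid="p01", trial=2, onset=0, offset=300),
            make_event(pid="p02", onset=0, offset=400),
        ]
    )
    tc = bin_events(ev, "fixation_duration_ms")
    assert tc.table["mean"].iloc[0] == pytest.approx((250 + 400) / 2)
    assert tc.table["n_participants"].iloc[0] == 2


def test_no_events_raises():
    with pytest.raises(ValueError, match="no fixation"):
        bin_events(make_events([make_event(kind="saccade", amp=2.0)]), "fixation_duration_ms")


def test_saccade_measure_uses_amplitude():
    ev = make_events([make_event(kind="saccade", onset=700, offset=740, amp=6.5)])
    tc = bin_events(ev, "saccade_amplitude_deg")
    assert tc.table["mean"].iloc[0] == pytest.approx(6.5)
    assert list(tc.table["bin"]) == [2]


# ------------------------------------------------------------------- fits


def test_noiseless_recovery_to_1e6():
    tc = synthetic_timecourse(300.0, -0.2)
    fit = fit_asymptote(tc)
    assert fit.converged
    assert fit.b == pytest.approx(300.0, abs=1e-6)
    assert fit.a == pytest.approx(-0.2, abs=1e-6)


def test_nls_matches_loglinear_ols_on_noiseless_data():
    """On exact-model data, NLS and the closed-form OLS of log(y) on 1/t
    find the same solution (the independent oracle for the fitter)."""
    tc = synthetic_timecourse(305.3, -0.23)
    t = tc.table["t_s"].to_numpy()
    y = tc.table["mean"].to_numpy()
    slope, intercept = np.polyfit(1.0 / t, np.log(y), 1)
    fit = fit_asymptote(tc)
    assert fit.b == pytest.approx(math.exp(intercept), abs=1e-6)
    assert fit.a == pytest.approx(slope, abs=1e-6)


def test_skip_bins_excludes_early_bins():
    tc = synthetic_timecourse(5.7, 0.4)
    # corrupt the first two bins (the pre-peak rise the model cannot express)
    tc.table.loc[0, "mean"] = 3.0
    tc.table.loc[1, "mean"] = 5.0
    fit = fit_asymptote(tc, skip_bins=2)
    assert fit.b == pytest.approx(5.7, abs=1e-6)
    assert fit.a == pytest.approx(0.4, abs=1e-6)
    assert fit.skip_bins == 2


def test_fit_invariant_to_bin_reordering():
    tc = synthetic_timecourse(300.0, -0.2)
    shuffled = TimeCourse(
        tc.measure, tc.bin_ms, tc.table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    )
    f1, f2 = fit_asymptote(tc), fit_asymptote(shuffled)
    assert f1.b == pytest.approx(f2.b, abs=1e-9)
    assert f1.a == pytest.approx(f2.a, abs=1e-9)


def test_fit_requires_enough_bins():
    tc = synthetic_timecourse(300.0, -0.2, n_bins=5)
    with pytest.raises(ValueError, match="at least 4"):
        fit_asymptote(tc, skip_bins=2)


def test_estimator_interface():
    model = AsymptoteModel()
    t = np.arange(1, 11) * 0.5
    model.fit(t, asymptote_curve(t, 280.0, -0.15))
    assert model.b_ == pytest.approx(280.0, abs=1e-6)
    np.testing.assert_allclose(model.predict([2.0]), asymptote_curve(2.0, 280.0, -0.15))
    assert model.get_params()["skip_bins"] == 0
    with pytest.raises(ValueError):
        model.predict([-1.0])


# ---------------------------------------------------------------- predict


def test_predict_published_pooled_curve_at_half_second():
    fit = AsymptoteFit(b=305.3, a=-0.23, b_ci=(287.1, 323.6), skip_bins=0,
                       residual_sse=0.0, converged=True)
    assert predict(fit, 0.5) == pytest.approx(192.7, abs=0.05)


def test_predict_limits():
    fit = AsymptoteFit(b=305.3, a=-0.23, b_ci=(math.nan, math.nan), skip_bins=0,
                       residual_sse=0.0, converged=True)
    assert predict(fit, 1e9) == pytest.approx(305.3, abs=1e-6)
    flat = AsymptoteFit(b=305.3, a=0.0, b_ci=(math.nan, math.nan), skip_bins=0,
                        residual_sse=0.0, converged=True)
    for t in (0.5, 1.0, 7.0):
        assert predict(flat, t) == pytest.approx(305.3)


def test_predict_rejects_nonpositive_time():
    fit = AsymptoteFit(b=300, a=-0.2, b_ci=(0, 0), skip_bins=0, residual_sse=0, converged=True)
    with pytest.raises(ValueError):
        predict(fit, 0.0)


@pytest.mark.parametrize("a, increasing", [(-0.2, True), (0.4, False)])
def test_curve_monotonicity(a, increasing):
    t = np.linspace(0.5, 20, 200)
    y = asymptote_curve(t, 300.0, a)
    diffs = np.diff(y)
    assert np.all(diffs > 0) if increasing else np.all(diffs < 0)


# ------------------------------------------------------------- reach time


def _tc_with_cis(b, a, half_width, n_bins=14):
    tc = synthetic_timecourse(b, a, n_bins=n_bins, half_width=half_width)
    return tc


def test_reach_time_first_qualifying_bin():
    tc = synthetic_timecourse(300.0, -0.2, half_width=5.0)
    # CIs of bins 1-6 constructed to exclude b, bin 7 to contain it
    tbl = tc.table
    tbl["ci_lo"] = tbl["mean"] - 1.0
    tbl["ci_hi"] = tbl["mean"] + 1.0
    tbl.loc[6, "ci_hi"] = 301.0
    tbl.loc[6, "ci_lo"] = 299.0
    fit = AsymptoteFit(300.0, -0.2, (299, 301), 0, 0.0, True)
    assert reach_time(fit, tc) == pytest.approx(3.5)


def test_reach_time_first_bin_and_not_found():
    tc = synthetic_timecourse(300.0, -0.2, half_width=500.0)
    fit = AsymptoteFit(300.0, -0.2, (299, 301), 0, 0.0, True)
    assert reach_time(fit, tc) == pytest.approx(0.5)  # b inside bin 1's wide CI
    narrow = synthetic_timecourse(300.0, -0.2, half_width=1e-9)
    assert reach_time(fit, narrow) is None  # never found, never an exception


def test_reach_time_requires_convergence():
    tc = synthetic_timecourse(300.0, -0.2)
    fit = AsymptoteFit(300.0, -0.2, (299, 301), 0, 0.0, converged=False)
    with pytest.raises(ValueError, match="converged"):
        reach_time(fit, tc)


def test_reach_time_nondecreasing_in_acceleration_magnitude():
    """Slower approach to asymptote (larger |a|) never reaches it earlier,
    on noiseless curves with fixed b and CI half-width."""
    times = []
    for a in (-0.02, -0.05, -0.1, -0.2):
        tc = synthetic_timecourse(300.0, a, n_bins=40, half_width=3.0)
        fit = fit_asymptote(tc)
        times.append(reach_time(fit, tc))
    assert all(t is not None for t in times)
    assert all(t2 >= t1 for t1, t2 in zip(times, times[1:]))
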