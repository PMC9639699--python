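import math

import numpy as np
import pandas as pd
import pytest

from ambifocal.detection import (
    DetectionParams,
    SaccadeDetector,
    compute_kinematics,
    detect_blinks,
    detect_saccades,
    segment_fixations,
)
from ambifocal.geometry import ScreenGeometry, angular_distance, deg_to_px, px_to_deg
from ambifocal.types import Blink, Saccade

GEO = ScreenGeometry()
PARAMS = DetectionParams()


def make_samples(x_deg, y_deg, pupil=None, t0=0):
    n = len(x_deg)
    x_px, y_px = deg_to_px(np.asarray(x_deg, float), np.asarray(y_deg, float), GEO)
    return pd.DataFrame(
        {
            "t_ms": np.arange(t0, t0 + n, dtype=np.int64),
            "x_px": x_px,
            "y_px": y_px,
            "pupil": np.full(n, 1000.0) if pupil is None else np.asarray(pupil, float),
        }
    )


def constant_samples(n, x=0.0, y=0.0):
    return make_samples(np.full(n, x), np.full(n, y))


def ramp_samples(n, start_ms, dur_ms, amp_deg, axis="x"):
    """Fixation, then a linear position ramp of amp_deg over dur_ms, then
    fixation at the new position."""
    pos = np.zeros(n)
    ramp = np.linspace(0, amp_deg, dur_ms + 1)
    pos[start_ms : start_ms + dur_ms + 1] = ramp
    pos[start_ms + dur_ms + 1 :] = amp_deg
    if axis == "x":
        return make_samples(pos, np.zeros(n))
    return make_samples(np.zeros(n), pos)


# ---------------------------------------------------------------- blinks


def test_no_missing_pupil_means_no_blinks():
    assert detect_blinks(constant_samples(100)) == []


def test_blink_run_extraction_half_open():
    s = constant_samples(6000)
    s.loc[(s.t_ms >= 5000) & (s.t_ms <= 5120), "pupil"] = 0.0
    assert detect_blinks(s) == [Blink(5000, 5121)]


def test_blink_merge_gap():
    s = constant_samples(6000)
    s.loc[(s.t_ms >= 5000) & (s.t_ms <= 5050), "pupil"] = np.nan
    s.loc[(s.t_ms >= 5060) & (s.t_ms <= 5100), "pupil"] = np.nan
    assert detect_blinks(s, merge_gap_ms=20) == [Blink(5000, 5101)]
    assert detect_blinks(s, merge_gap_ms=0) == [Blink(5000, 5051), Blink(5060, 5101)]


# ------------------------------------------------------------ kinematics


def test_constant_position_has_zero_kinematics():
    kin = compute_kinematics(constant_samples(50), GEO, PARAMS)
    assert np.allclose(kin["speed_deg_s"], 0)
    assert np.allclose(kin["accel_deg_s2"], 0)


def test_linear_ramp_interior_speed():
    # 10 deg over 20 ms -> 500 deg/s in the ramp interior
    kin = compute_kinematics(ramp_samples(100, 40, 20, 10.0), GEO, PARAMS)
    interior = kin["speed_deg_s"].to_numpy()[45:55]
    assert np.allclose(interior, 500.0, atol=1e-6)


def test_speed_is_isotropic():
    kx = compute_kinematics(ramp_samples(100, 40, 20, 1.0, axis="x"), GEO, PARAMS)
    ky = compute_kinematics(ramp_samples(100, 40, 20, 1.0, axis="y"), GEO, PARAMS)
    np.testing.assert_allclose(
        kx["speed_deg_s"].to_numpy(), ky["speed_deg_s"].to_numpy(), atol=1e-9
    )


def test_kinematics_input_validation():
    with pytest.raises(ValueError, match="at least 5"):
        compute_kinematics(constant_samples(3), GEO, PARAMS)
    bad = constant_samples(20)
    bad.loc[10:, "t_ms"] += 3
    with pytest.raises(ValueError, match="non-uniform"):
        compute_kinematics(bad, GEO, PARAMS)


# -------------------------------------------------------------- saccades


def test_constant_position_yields_no_saccades():
    assert detect_saccades(constant_samples(200), GEO, PARAMS) == []


def test_planted_ramp_detected_accurately():
    s = ramp_samples(2000, 1000, 20, 10.0)
    out = detect_saccades(s, GEO, PARAMS)
    assert len(out) == 1
    sac = out[0]
    assert abs(sac.onset_ms - 1000) <= 2
    # The |accel| offset criterion holds the candidate open one sample past
    # the velocity run at an instantaneous stop, hence <= 3 rather than 2.
    assert abs(sac.offset_ms - 1020) <= 3
    assert abs(sac.amplitude_deg - 10.0) <= 0.05


def test_slow_drift_below_velocity_threshold_ignored():
    # 10 deg over 1 s = 10 deg/s < 30 deg/s despite a 10-deg deflection
    s = ramp_samples(2000, 500, 1000, 10.0)
    assert detect_saccades(s, GEO, PARAMS) == []


def test_no_detected_saccade_overlaps_a_blink():
    """A blink mid-movement masks its samples, so no candidate can span it
    and the full-amplitude saccade is never reported as a single event."""
    s = ramp_samples(2000, 1000, 20, 10.0)
    s.loc[(s.t_ms >= 1005) & (s.t_ms <= 1010), "pupil"] = 0.0
    blinks = detect_blinks(s)
    out = detect_saccades(s, GEO, PARAMS, blinks=blinks)
    for sac in out:
        assert not (sac.onset_ms < blinks[0].offset_ms and blinks[0].onset_ms < sac.offset_ms)
        assert sac.amplitude_deg < 9.0  # only fragments survive the mask


def test_rotating_scanpath_90deg_preserves_events():
    """Swap-and-negate in degree space (a 90-degree rotation, square screen)
    preserves event counts and amplitudes to machine precision."""
    geo = ScreenGeometry(width_px=800, height_px=800, half_width_deg=12.0, half_height_deg=12.0)
    rng = np.random.default_rng(42)
    x = np.zeros(3000)
    y = np.zeros(3000)
    pos = np.array([0.0, 0.0])
    cursor = 100
    for amp, dur in [(6.0, 30), (3.0, 25), (8.0, 40)]:
        theta = rng.uniform(0, 2 * math.pi)
        step = np.array([math.cos(theta), math.sin(theta)]) * amp
        ramp = np.linspace(0, 1, dur + 1)
        x[cursor : cursor + dur + 1] = pos[0] + step[0] * ramp
        y[cursor : cursor + dur + 1] = pos[1] + step[1] * ramp
        pos = pos + step
        x[cursor + dur + 1 :] = pos[0]
        y[cursor + dur + 1 :] = pos[1]
        cursor += 700

    def detect_xy(xd, yd):
        xpx, ypx = deg_to_px(xd, yd, geo)
        s = pd.DataFrame(
            {"t_ms": np.arange(len(xd), dtype=np.int64), "x_px": xpx, "y_px": ypx,
             "pupil": np.full(len(xd), 1000.0)}
        )
        return detect_saccades(s, geo, PARAMS)

    base = detect_xy(x, y)
    rot = detect_xy(-y, x)  # rotate 90 degrees
    assert len(base) == len(rot) == 3
    for a, b in zip(base, rot):
        assert a.onset_ms == b.onset_ms and a.offset_ms == b.offset_ms
        assert abs(a.amplitude_deg - b.amplitude_deg) < 1e-9


def test_noise_robustness_of_planted_saccade():
    """With gaussian positional noise (sd 0.05 deg) a planted 8-deg saccade
    is still found with onset error <= 3 ms."""
    rng = np.random.default_rng(7)
    s = ramp_samples(2000, 1000, 35, 8.0)
    xd, yd = px_to_deg(s["x_px"].to_numpy(), s["y_px"].to_numpy(), GEO)
    xd = xd + rng.normal(0, 0.05, len(s))
    yd = yd + rng.normal(0, 0.05, len(s))
    noisy = make_samples(xd, yd)
    out = detect_saccades(noisy, GEO, PARAMS)
    big = [sc for sc in out if sc.amplitude_deg > 5]
    assert len(big) == 1
    assert abs(big[0].onset_ms - 1000) <= 3


# ------------------------------------------------------------- fixations


def test_no_events_gives_single_trial_spanning_fixation():
    s = constant_samples(3000)
    fixes = segment_fixations(s, [], [], 3000)
    assert len(fixes) == 1
    assert (fixes[0].onset_ms, fixes[0].offset_ms) == (0, 3000)
    assert fixes[0].preceding_saccade_amplitude_deg is None


def test_fixations_are_complement_of_saccade():
    s = constant_samples(3000)
    sac = Saccade(1000, 1030, 512, 384, 600, 384, amplitude_deg=2.5)
    fixes = segment_fixations(s, [sac], [], 3000)
    assert [(f.onset_ms, f.offset_ms) for f in fixes] == [(0, 1000), (1030, 3000)]
    assert fixes[0].preceding_saccade_amplitude_deg is None
    assert fixes[1].preceding_saccade_amplitude_deg == pytest.approx(2.5)


def test_fixation_after_blink_has_no_preceding_amplitude():
    s = constant_samples(3000)
    sac = Saccade(1000, 1030, 512, 384, 600, 384, amplitude_deg=2.5)
    blink = Blink(1030, 1200)
    fixes = segment_fixations(s, [sac], [blink], 3000)
    assert [(f.onset_ms, f.offset_ms) for f in fixes] == [(0, 1000), (1200, 3000)]
    assert fixes[1].preceding_saccade_amplitude_deg is None


def test_overlapping_input_events_rejected():
    s = constant_samples(3000)
    sacs = [
        Saccade(1000, 1050, 512, 384, 600, 384, amplitude_deg=2.5),
        Saccade(1040, 1090, 512, 384, 600, 384, amplitude_deg=2.5),
    ]
    with pytest.raises(ValueError, match="overlap"):
        segment_fixations(s, sacs, [], 3000)


def test_events_partition_the_trial():
    from ambifocal import SimulationConfig, simulate_trial
    from ambifocal.detection import detect_trial

    cfg = SimulationConfig(seed=9, noise_sd_deg=0.0)
    samples, _ = simulate_trial(cfg, "control", seed=21)
    tr = detect_trial(samples)
    events = (
        [(f.onset_ms, f.offset_ms) for f in tr.fixations]
        + [(s.onset_ms, s.offset_ms) for s in tr.saccades]
        + [(b.onset_ms, b.offset_ms) for b in tr.blinks]
    )
    total = sum(off - on for on, off in events)
    n_boundaries = len(events)
    assert abs(total - cfg.trial_ms) <= n_boundaries  # one sample per boundary


def test_saccade_detector_estimator_roundtrip():
    from ambifocal.io_formats import TrialSamples
    from ambifocal.types import TrialMeta

    s = ramp_samples(3000, 1000, 20, 10.0)
    meta = TrialMeta("p01", 1, "control", "natural", trial_duration_ms=3000)
    det = SaccadeDetector()
    events = det.fit().transform(TrialSamples(meta=meta, samples=s))
    assert set(events["event_kind"]) == {"fixation", "saccade"}
    assert det.get_params()["merge_gap_ms"] == 0
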