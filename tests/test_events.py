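"""Velocity estimation, saccade detection rules and the desaccade mask."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculodecode.events import (
    DetectionParams,
    SaccadeEvent,
    compute_velocity,
    desaccade_mask,
    detect_saccades,
    interpolate_blinks,
)
from oculodecode.io import EyeTrace
from conftest import make_clean_trace, inject_saccade


class TestComputeVelocity:
    def test_linear_ramp_exact(self):
        n, fs = 500, 500.0
        t = np.arange(n) / fs
        trace = make_clean_trace(n, fs, x=10.0 * t)
        vx, vy, speed = compute_velocity(trace)
        np.testing.assert_allclose(vx[3:-3], 10.0, atol=1e-9)
        np.testing.assert_allclose(speed[3:-3], 10.0, atol=1e-9)
        assert np.isnan(speed[:3]).all() and np.isnan(speed[-3:]).all()

    def test_constant_position_zero_speed(self):
        trace = make_clean_trace(200)
        _, _, speed = compute_velocity(trace)
        np.testing.assert_allclose(speed[3:-3], 0.0, atol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_velocity(make_clean_trace(4))

    def test_peak_speed_matches_injected_peak_velocity(self):
        # the smoothing differentiator attenuates the peak of a 50 ms
        # profile by ~2-3% (the price of its noise robustness); the boxcar
        # adds ~1% more
        trace = make_clean_trace(800)
        wf = inject_saccade(trace, 300, 10.0, 0.0)
        _, _, sharp = compute_velocity(trace, DetectionParams(smooth_window=1))
        assert np.nanmax(sharp) == pytest.approx(wf.peak_vel_deg_s, rel=0.03)
        _, _, smoothed = compute_velocity(trace)
        assert np.nanmax(smoothed) == pytest.approx(wf.peak_vel_deg_s, rel=0.05)


class TestDetectSaccades:
    def test_single_saccade_kinematics(self):
        trace = make_clean_trace(800)
        inject_saccade(trace, 300, 8.0, 0.0)
        events = detect_saccades(trace, mode="fixed")
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude_deg == pytest.approx(8.0, abs=0.05)
        assert abs(ev.onset_ms - 300 * 2.0) <= 4.0
        assert ev.peak_vel_deg_s >= ev.mean_vel_deg_s
        assert not ev.is_microsaccade

    def test_fixation_drift_below_threshold_yields_nothing(self, rng):
        n = 1000
        drift = np.cumsum(rng.normal(0, 0.002, n))  # slow wander
        trace = make_clean_trace(n, x=drift)
        assert detect_saccades(trace, mode="fixed") == []

    def test_merge_rule(self):
        # 100 ms apart -> two events; 10 ms apart with 20 ms merge -> one
        far = make_clean_trace(1200)
        inject_saccade(far, 300, 4.0, 0.0)
        inject_saccade(far, 300 + 50 + 14, 4.0, 180.0)  # ~100 ms after offset
        assert len(detect_saccades(far, mode="fixed")) == 2
        near = make_clean_trace(1200)
        inject_saccade(near, 300, 4.0, 0.0)
        inject_saccade(near, 300 + 17 + 4, 4.0, 0.0)  # ~8 ms gap
        assert len(detect_saccades(near, mode="fixed")) == 1

    def test_microsaccade_flag_respects_amplitude_bound(self):
        trace = make_clean_trace(800)
        inject_saccade(trace, 200, 0.8, 90.0)
        inject_saccade(trace, 500, 3.0, 270.0)
        events = detect_saccades(trace, mode="adaptive")
        flags = {round(e.amplitude_deg, 1): e.is_microsaccade for e in events}
        assert flags[0.8] is True and flags[3.0] is False

    def test_downward_flag_and_angle_folding(self):
        trace = make_clean_trace(800)
        inject_saccade(trace, 300, 5.0, 250.0)
        (ev,) = detect_saccades(trace, mode="fixed")
        assert ev.is_downward
        assert ev.angle_from_horizontal_deg == pytest.approx(70.0, abs=3.0)
        assert 0.0 <= ev.angle_from_horizontal_deg <= 90.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(0.0, 360.0))
    def test_rotation_equivariance(self, angle):
        """Rotating the trace rotates directions and preserves amplitudes."""
        base = make_clean_trace(700)
        inject_saccade(base, 250, 6.0, 0.0)
        rad = np.deg2rad(angle)
        rot = make_clean_trace(
            700,
            x=base.x_deg * np.cos(rad) - base.y_deg * np.sin(rad),
            y=base.x_deg * np.sin(rad) + base.y_deg * np.cos(rad),
        )
        (e0,) = detect_saccades(base, mode="fixed")
        (e1,) = detect_saccades(rot, mode="fixed")
        assert e1.amplitude_deg == pytest.approx(e0.amplitude_deg, rel=1e-6)
        dd = (e1.direction_deg - e0.direction_deg - angle) % 360.0
        assert min(dd, 360.0 - dd) < 1e-6

    def test_adaptive_false_positive_rate_on_gaussian_drift(self, rng):
        """lambda=6 elliptic threshold: <= 0.2 events/s on pure noise."""
        total_events, total_s = 0, 0.0
        for _ in range(20):
            n = 2500  # 5 s at 500 Hz
            trace = make_clean_trace(
                n, x=rng.normal(0, 0.02, n), y=rng.normal(0, 0.02, n)
            )
            total_events += len(detect_saccades(trace, mode="adaptive"))
            total_s += n / 500.0
        assert total_events / total_s <= 0.2

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            detect_saccades(make_clean_trace(100), mode="magic")


class TestDesaccadeMask:
    def test_no_events_all_included(self):
        trace = make_clean_trace(300)
        assert desaccade_mask(trace, []).all()

    def test_pad_arithmetic(self):
        # a 20-sample (40 ms) event extent padded by 10 ms (5 samples) each
        # side excludes exactly 30 samples at 500 Hz
        trace = make_clean_trace(400)
        ev = SaccadeEvent(
            onset_ms=200.0, offset_ms=238.0, duration_ms=38.0, amplitude_deg=3.0,
            peak_vel_deg_s=200.0, mean_vel_deg_s=80.0, avg_vel_deg_s=80.0,
            direction_deg=0.0, angle_from_horizontal_deg=0.0, is_downward=False,
            is_microsaccade=False, onset_idx=100, offset_idx=119,
        )
        mask = desaccade_mask(trace, [ev], pad_ms=10.0)
        assert (~mask).sum() == 30

    def test_overlapping_pads_union(self):
        trace = make_clean_trace(400)
        mk = lambda i0, i1: SaccadeEvent(
            onset_ms=i0 * 2.0, offset_ms=i1 * 2.0, duration_ms=(i1 - i0) * 2.0,
            amplitude_deg=1.0, peak_vel_deg_s=100.0, mean_vel_deg_s=50.0,
            avg_vel_deg_s=50.0, direction_deg=0.0, angle_from_horizontal_deg=0.0,
            is_downward=False, is_microsaccade=True, onset_idx=i0, offset_idx=i1,
        )
        mask = desaccade_mask(trace, [mk(100, 110), mk(108, 120)], pad_ms=10.0)
        assert (~mask).sum() == (120 + 5) - (100 - 5) + 1


def test_blink_interpolation_and_long_gap_flag():
    t = np.arange(200) * 2.0
    x = np.linspace(0, 1, 200)
    short = x.copy()
    short[50:60] = np.nan  # 20 ms gap
    filled, flag = interpolate_blinks(short, t, max_gap_ms=50.0)
    assert not flag
    np.testing.assert_allclose(filled, x, atol=1e-9)
    long = x.copy()
    long[50:90] = np.nan  # 80 ms gap
    _, flag = interpolate_blinks(long, t, max_gap_ms=50.0)
    assert flag
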