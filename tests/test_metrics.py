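"""Task metrics: trial scoring, pursuit gains, fixation statistics,
free-viewing statistics, aggregation and the speed-accuracy correlation."""

import dataclasses
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculodecode.events import DetectionParams, detect_saccades
from oculodecode.io import EyeTrace, InsufficientDataError, TrialMeta
from oculodecode.metrics import (
    aggregate_session,
    bcea,
    extract_session_features,
    fixation_metrics,
    freeview_metrics,
    pursuit_linear_metrics,
    pursuit_lissajous_metrics,
    score_saccade_trial,
    speed_accuracy_correlation,
)
from oculodecode.synth import GeneratorConfig, simulate_session
from oculodecode.io import SessionFeatures, FEATURE_KEYS
from conftest import make_clean_trace, inject_saccade


# ---------------------------------------------------------------------------
# trial scoring


def _score_parity_counts(cfg, subject, state, n_sessions=3):
    agree = total = 0
    for i in range(n_sessions):
        s = simulate_session(cfg, subject, state, i)
        for trace, meta in s.trials:
            if meta.task not in ("anti_saccade", "pro_saccade", "delayed_saccade"):
                continue
            events = detect_saccades(trace, mode="fixed")
            sc = score_saccade_trial(trace, meta, events)
            total += 1
            agree += sc.correct == meta.ground_truth["correct"]
    return agree, total


def test_scoring_matches_generated_outcome_exactly():
    """On noiseless sessions every trial's scored correctness equals the
    generator's injected outcome (anti rule, pro rule, delay breaks,
    no-response trials)."""
    cfg = dataclasses.replace(
        GeneratorConfig(seed=17).noiseless(),
        tasks=("anti_saccade", "pro_saccade", "delayed_saccade"),
    )
    for state in ("saline", "pcp"):
        agree, total = _score_parity_counts(cfg, "Y", state)
        assert total > 100
        assert agree == total


def test_delay_break_scored_incorrect():
    cfg = dataclasses.replace(
        GeneratorConfig(seed=23).noiseless(), tasks=("delayed_saccade",)
    )
    cfg.states["pcp"] = replace(cfg.states["pcp"], delay_break_p=0.9)
    s = simulate_session(cfg, "Y", "pcp", 0)
    broke_seen = 0
    for trace, meta in s.trials:
        if not meta.ground_truth["broke"]:
            continue
        broke_seen += 1
        sc = score_saccade_trial(trace, meta, detect_saccades(trace, mode="fixed"))
        assert sc.correct is False and sc.broke_fixation
    assert broke_seen >= 5


def test_programmed_accuracy_recovered_binomially():
    """200 anti trials at programmed accuracy 0.75 -> measured accuracy
    inside the binomial 95% CI."""
    cfg = dataclasses.replace(GeneratorConfig(seed=29), tasks=("anti_saccade",))
    cfg.trials = replace(cfg.trials, anti=200)
    for st_name in cfg.states:
        cfg.states[st_name] = replace(cfg.states[st_name], anti_acc=0.75)
    cfg.scatter = replace(cfg.scatter, acc_logit=0.0, latent_acc_beta=0.0)
    s = simulate_session(cfg, "Y", "saline", 0)
    feats = extract_session_features(s.trials)
    p_hat = feats.features["anti_accuracy"]
    half = 1.96 * np.sqrt(0.75 * 0.25 / 200)
    assert abs(p_hat - 0.75) <= half + 0.02  # CI plus the no-response rate


# ---------------------------------------------------------------------------
# pursuit


def _linear_track(gain, n=4000, fs=500.0, speed=10.0, span=8.0):
    t = np.arange(n) / fs
    d = speed * np.maximum(t - 0.2, 0.0)
    m = np.mod(d + span, 4 * span)
    tx = np.where(t >= 0.2, np.where(m < 2 * span, m - span, 3 * span - m), 0.0)
    trace = make_clean_trace(n, fs, x=gain * tx, tx=tx)
    trace.events["target_on"] = int(0.2 * fs)
    return trace


def test_linear_gain_identity_tracking():
    trace = _linear_track(1.0)
    gain, rate = pursuit_linear_metrics(trace, [])
    assert gain == pytest.approx(1.0, abs=0.01)
    assert rate == 0.0


def test_linear_gain_stationary_eye_zero():
    trace = _linear_track(0.0)
    gain, _ = pursuit_linear_metrics(trace, [])
    assert gain == pytest.approx(0.0, abs=0.01)


def test_linear_gain_recovery_with_catchups():
    cfg = dataclasses.replace(GeneratorConfig(seed=31), tasks=("linear_pursuit",))
    cfg.scatter = replace(cfg.scatter, gain=0.0)
    for st_name in cfg.states:
        cfg.states[st_name] = replace(cfg.states[st_name], lin_gain=0.7)
    errs = []
    for i in range(4):
        s = simulate_session(cfg, "Y", "saline", i)
        f = extract_session_features(s.trials)
        errs.append(f.features["lin_gain"] - 0.7)
    assert np.max(np.abs(errs)) < 0.03


def _lissajous_trace(gx, gy, phase=0.0, n=5000, fs=500.0, ax=8.0, ay=8.0,
                     fx=0.2, fy=0.3):
    t = np.arange(n) / fs
    ts = np.maximum(t - 0.2, 0.0)
    tx = ax * np.sin(2 * np.pi * fx * ts)
    ty = ay * np.sin(2 * np.pi * fy * ts)
    # phase-lagged eye; the onset discontinuity falls inside the settle
    # window the fit excludes
    ex = np.where(ts > 0, gx * ax * np.sin(2 * np.pi * fx * ts - phase), 0.0)
    ey = np.where(ts > 0, gy * ay * np.sin(2 * np.pi * fy * ts - phase), 0.0)
    trace = make_clean_trace(n, fs, x=ex, y=ey, tx=tx, ty=ty)
    trace.events["target_on"] = int(0.2 * fs)
    return trace


def test_lissajous_identity_gains():
    fx, fy, rate = pursuit_lissajous_metrics(_lissajous_trace(1.0, 1.0), [])
    assert fx.gain == pytest.approx(1.0, abs=0.01)
    assert fy.gain == pytest.approx(1.0, abs=0.01)
    assert abs(fx.phase_rad) < 0.02 and abs(fy.phase_rad) < 0.02
    assert rate == 0.0


def test_lissajous_programmed_gains_and_phase():
    fx, fy, _ = pursuit_lissajous_metrics(
        _lissajous_trace(0.8, 0.5, phase=np.pi / 2), []
    )
    assert fx.gain == pytest.approx(0.8, abs=0.05)
    assert fy.gain == pytest.approx(0.5, abs=0.05)
    assert fx.phase_rad == pytest.approx(np.pi / 2, abs=0.1)


def test_lissajous_frequency_inference_matches_known_params():
    trace = _lissajous_trace(0.9, 0.7)
    inferred = pursuit_lissajous_metrics(trace, [])
    known = pursuit_lissajous_metrics(
        trace, [], target_params={"fx_hz": 0.2, "fy_hz": 0.3}
    )
    assert inferred[0].gain == pytest.approx(known[0].gain, abs=0.01)
    assert inferred[1].gain == pytest.approx(known[1].gain, abs=0.01)


# ---------------------------------------------------------------------------
# fixation


class TestBCEA:
    def test_identical_samples_zero(self):
        x = np.full(500, 1.5)
        assert bcea(x, x) == 0.0

    def test_gaussian_closed_form(self, rng):
        # sigma=1, rho=0, P=0.68: 2 k pi = 2 * 1.1394 * pi ~ 7.16 deg^2
        x = rng.normal(0, 1, 10_000)
        y = rng.normal(0, 1, 10_000)
        assert bcea(x, y, 0.68) == pytest.approx(7.1589, rel=0.05)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(angle=st.floats(0.0, np.pi), scale=st.floats(0.5, 3.0))
    def test_rotation_invariance_and_quadratic_scaling(self, angle, scale):
        rng = np.random.default_rng(99)
        x = rng.normal(0, 1.0, 4000)
        y = rng.normal(0, 0.5, 4000) + 0.3 * x
        base = bcea(x, y)
        xr = x * np.cos(angle) - y * np.sin(angle)
        yr = x * np.sin(angle) + y * np.cos(angle)
        assert bcea(xr, yr) == pytest.approx(base, rel=1e-9)
        assert bcea(scale * x, scale * y) == pytest.approx(
            scale**2 * base, rel=1e-9
        )


def test_fixation_metrics_pupil_windows_and_micro_angles(rng):
    n, fs = 1500, 500.0  # 3 s
    t = np.arange(n) / fs
    pupil = 1000.0 * (1 - 0.2 * (1 - np.exp(-t / 0.6)))
    trace = make_clean_trace(n, fs, pupil=pupil)
    inject_saccade(trace, 300, 0.5, 0.0)    # horizontal
    inject_saccade(trace, 800, 0.5, 180.0)  # horizontal
    events = detect_saccades(trace, mode="adaptive")
    stats, agg = fixation_metrics(trace, events)
    assert agg["ms_angle_deg"] == pytest.approx(0.0, abs=2.0)
    t_ms = trace.t_ms - trace.t_ms[0]
    assert stats.pupil_baseline == pytest.approx(np.mean(pupil[t_ms < 200]), rel=1e-6)
    assert stats.pupil_size == pytest.approx(np.mean(pupil[t_ms < 500]), rel=1e-6)
    assert stats.pupil_response == pytest.approx(
        np.mean(pupil[t_ms >= t_ms[-1] - 1000]) - np.mean(pupil[t_ms < 200]),
        rel=1e-6,
    )
    assert stats.pupil_response < 0  # constriction

    vert = make_clean_trace(n, fs, pupil=pupil)
    inject_saccade(vert, 400, 0.5, 90.0)
    inject_saccade(vert, 900, 0.5, 270.0)
    _, agg_v = fixation_metrics(vert, detect_saccades(vert, mode="adaptive"))
    assert agg_v["ms_angle_deg"] == pytest.approx(90.0, abs=2.0)


def test_fixation_metrics_needs_enough_samples():
    with pytest.raises(InsufficientDataError):
        fixation_metrics(make_clean_trace(80), [])


# ---------------------------------------------------------------------------
# free viewing


def test_freeview_no_saccades_gives_missing_stats():
    fv = freeview_metrics(make_clean_trace(1000), [])
    assert fv.sacc_rate_hz == 0.0
    assert np.isnan(fv.amp_median_deg) and np.isnan(fv.angle_deg)


def test_freeview_rate_recovery():
    cfg = dataclasses.replace(GeneratorConfig(seed=37), tasks=("free_viewing",))
    rates_m, rates_g = [], []
    for i in range(6):
        s = simulate_session(cfg, "Y", "saline", i)
        f = extract_session_features(s.trials)
        rates_m.append(f.features["fv_sacc_rate"])
        rates_g.append(s.ground_truth["features"]["fv_sacc_rate"])
    assert np.mean(rates_m) == pytest.approx(np.mean(rates_g), abs=0.2)


# ---------------------------------------------------------------------------
# aggregation & correlation


def test_aggregate_single_trial_identity():
    row = {"lin_gain": 0.8, "lin_sacc_rate": 1.5}
    out = aggregate_session({"linear_pursuit": [row]})
    assert out == pytest.approx(row)


def test_aggregate_skips_nan():
    rows = [{"a": 1.0}, {"a": float("nan")}, {"a": 3.0}]
    assert aggregate_session({"t": rows})["a"] == pytest.approx(2.0)


def _sf(state, sid, acc, rt):
    feats = {k: 0.0 for k in FEATURE_KEYS}
    feats["anti_accuracy"] = acc
    feats["anti_rt_ms"] = rt
    return SessionFeatures(subject="Y", state=state, session_id=sid, features=feats)


def test_speed_accuracy_exact_line_r_one():
    feats = [_sf("saline", f"s{i}", 0.5 + 0.05 * i, 200.0 + 10 * i) for i in range(5)]
    assert speed_accuracy_correlation(feats)["saline"] == pytest.approx(1.0)


def test_speed_accuracy_degenerate_cases():
    # too few sessions and zero variance both map to NaN
    few = [_sf("pcp", "a", 0.5, 200.0), _sf("pcp", "b", 0.6, 210.0)]
    assert np.isnan(speed_accuracy_correlation(few)["pcp"])
    flat = [_sf("saline", f"s{i}", 0.5, 200.0 + i) for i in range(5)]
    assert np.isnan(speed_accuracy_correlation(flat)["saline"])
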