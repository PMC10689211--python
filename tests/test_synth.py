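"""Generator contracts: main-sequence waveforms, determinism, effect
directions in ground truth, and the oddball/AEP generative model."""

import dataclasses
from dataclasses import replace

import numpy as np
import pytest

from oculodecode.synth import (
    GeneratorConfig,
    MainSequenceParams,
    aep_template,
    make_oddball_sequence,
    simulate_aep_epochs,
    simulate_saccade,
    simulate_session,
)


class TestSimulateSaccade:
    def test_main_sequence_peak_velocity_closed_form(self):
        # v_max (1 - exp(-A/a_sat)) at A=10, v_max=500, a_sat=5
        ms = MainSequenceParams(v_max=500.0, a_sat=5.0)
        wf = simulate_saccade(10.0, 0.0, ms, 500.0)
        assert wf.peak_vel_deg_s == pytest.approx(500.0 * (1 - np.exp(-2.0)), rel=0.01)

    @pytest.mark.parametrize("amp", [0.3, 1.0, 5.0, 12.0])
    def test_net_amplitude_exact(self, amp):
        wf = simulate_saccade(amp, 30.0, MainSequenceParams(), 500.0)
        net = np.hypot(wf.dx[-1], wf.dy[-1])
        assert net == pytest.approx(amp, rel=0.005)

    def test_small_amplitude_limit_small_peak(self):
        wf = simulate_saccade(1e-3, 0.0, MainSequenceParams(), 500.0)
        assert wf.peak_vel_deg_s < 1.0

    def test_direction_180_reverses_displacement(self):
        wf = simulate_saccade(6.0, 180.0, MainSequenceParams(), 500.0)
        assert wf.dx[-1] == pytest.approx(-6.0, abs=1e-9)
        assert wf.dy[-1] == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            simulate_saccade(0.0, 0.0, MainSequenceParams(), 500.0)

    def test_duration_follows_linear_law(self):
        ms = MainSequenceParams(dur_intercept_ms=20.0, dur_slope_ms=3.0)
        wf = simulate_saccade(8.0, 0.0, ms, 500.0, dur_scale=1.1)
        assert wf.duration_ms == pytest.approx(1.1 * (20.0 + 3.0 * 8.0))


def test_session_determinism_byte_identical(tmp_path):
    from oculodecode.io import write_trace_file

    cfg = GeneratorConfig(seed=21)
    a = simulate_session(cfg, "N", "pcp", 3)
    b = simulate_session(cfg, "N", "pcp", 3)
    for (ta, _), (tb, _) in zip(a.trials, b.trials):
        np.testing.assert_array_equal(ta.x_deg, tb.x_deg)
        np.testing.assert_array_equal(ta.pupil_au, tb.pupil_au)
    write_trace_file(a.trials, tmp_path / "a.tsv")
    write_trace_file(b.trials, tmp_path / "b.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_unknown_state_or_subject_rejected():
    cfg = GeneratorConfig(seed=0)
    with pytest.raises(ValueError):
        simulate_session(cfg, "Z", "saline", 0)
    with pytest.raises(ValueError):
        simulate_session(cfg, "Y", "mdma", 0)


def test_ground_truth_effect_directions():
    """State means of generator ground truth are ordered the way the drugs
    shift each quantity (assertable without running any detection)."""
    cfg = dataclasses.replace(GeneratorConfig(seed=8), sessions_per_state=8)
    means = {}
    for state in ("saline", "pcp", "ketamine"):
        feats = [
            simulate_session(cfg, subj, state, i).ground_truth["features"]
            for subj in ("Y", "N")
            for i in range(cfg.sessions_per_state)
        ]
        means[state] = {k: np.mean([f[k] for f in feats]) for k in feats[0]}
    sal = means["saline"]
    for drug in ("pcp", "ketamine"):
        d = means[drug]
        assert d["anti_accuracy"] < sal["anti_accuracy"]
        assert d["anti_rt_ms"] > sal["anti_rt_ms"]
        assert d["anti_sacc_vel"] < sal["anti_sacc_vel"]
        assert d["anti_sacc_dur"] > sal["anti_sacc_dur"]
        assert d["lin_gain"] < sal["lin_gain"]
        assert d["lin_sacc_rate"] > sal["lin_sacc_rate"]
        assert d["lis_gain_x"] < sal["lis_gain_x"]
        assert d["lis_gain_y"] < sal["lis_gain_y"]
        assert d["lis_sacc_rate"] > sal["lis_sacc_rate"]
        assert d["ms_amp"] > sal["ms_amp"]
        assert d["ms_vel"] > sal["ms_vel"]
        assert d["ms_down_frac"] > sal["ms_down_frac"]
        assert d["pupil_size"] < sal["pupil_size"]
        assert abs(d["pupil_response"]) < abs(sal["pupil_response"])
        assert d["fv_sacc_rate"] < sal["fv_sacc_rate"]
    assert means["pcp"]["bcea_deg2"] > sal["bcea_deg2"]


def test_downward_microsaccade_fraction_drug_exceeds_saline():
    cfg = dataclasses.replace(
        GeneratorConfig(seed=13), sessions_per_state=20, tasks=("fixation",)
    )
    fracs = {}
    for state in ("saline", "pcp"):
        vals = [
            simulate_session(cfg, "Y", state, i).ground_truth["features"][
                "ms_down_frac"
            ]
            for i in range(20)
        ]
        fracs[state] = np.mean(vals)
    assert fracs["pcp"] > fracs["saline"] + 0.1


class TestAEPGenerator:
    def test_noiseless_state_gain_scales_peak_to_trough(self):
        cfg = GeneratorConfig(seed=0)
        cfg.states["ketamine"] = replace(cfg.states["saline"], aep_gain=1.3)
        a = simulate_aep_epochs(cfg, "saline", 80, 1500, "standard", 2, noise_sd_uv=0.0)
        b = simulate_aep_epochs(cfg, "ketamine", 80, 1500, "standard", 2, noise_sd_uv=0.0)
        ra = a.epochs[0].max() - a.epochs[0].min()
        rb = b.epochs[0].max() - b.epochs[0].min()
        assert rb / ra == pytest.approx(1.3, rel=1e-9)

    def test_unit_deviant_gain_gives_identical_expectation(self):
        cfg = GeneratorConfig(seed=0)
        cfg.states["saline"] = replace(cfg.states["saline"], deviant_gain=1.0)
        std = simulate_aep_epochs(cfg, "saline", 80, 1500, "standard", 1, noise_sd_uv=0.0)
        dev = simulate_aep_epochs(cfg, "saline", 80, 1500, "deviant", 1, noise_sd_uv=0.0)
        np.testing.assert_allclose(std.epochs, dev.epochs, atol=1e-12)

    def test_template_components_have_expected_polarity(self):
        cfg = GeneratorConfig(seed=0)
        t = cfg.aep.t_ms
        tpl = aep_template(t, cfg.aep)
        assert tpl[np.argmin(np.abs(t - 50))] > 0  # P50
        assert tpl[np.argmin(np.abs(t - 100))] < 0  # N100
        assert tpl[np.argmin(np.abs(t - 185))] > 0  # P200
        assert np.abs(tpl[t < 0]).max() < 0.05  # quiet pre-stimulus span

    def test_epoch_count_validated(self):
        cfg = GeneratorConfig(seed=0)
        with pytest.raises(ValueError):
            simulate_aep_epochs(cfg, "saline", 80, 1500, "standard", 0)
        with pytest.raises(ValueError):
            simulate_aep_epochs(cfg, "saline", 70, 1500, "standard", 5)


def test_oddball_sequence_constraints(rng):
    mask = make_oddball_sequence(rng, 500, deviant_frac=0.2, min_standards_between=2)
    assert mask.sum() == 100
    gaps = np.diff(np.flatnonzero(mask))
    assert gaps.min() >= 3  # at least two standards between deviants
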