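"""Synthetic two-subject, three-state oculomotor and EEG session generator.

The generator emulates the study design the analysis pipeline targets: two
macaque-like subjects with different baseline gaze habits perform a
seven-task battery (anti-saccade, pro-saccade, delayed saccade, linear
pursuit at 10 deg/s, Lissajous pursuit, fixation, free viewing) across
sessions recorded under three injection states (saline, PCP, ketamine).
Drug states shift each generated quantity in the direction the NMDA-
antagonist literature reports for these drugs: lower anti-saccade accuracy
with longer reaction times, slower and longer saccades, lower pursuit gain
with more catch-up saccades, larger and faster microsaccades biased toward
the lower visual field, less stable fixation (larger BCEA), smaller pupil
with a reduced pupillary constriction response, and amplified auditory
evoked potentials with a reduced mismatch-negativity contrast.

Saccades are synthesised from a main-sequence model: peak velocity
``v_max * (1 - exp(-A / a_sat))`` and duration ``intercept + slope * A``.
The velocity profile is ``sin(pi t / D) ** gamma``; the shape exponent
``gamma`` is solved per saccade so that amplitude, duration and peak
velocity are simultaneously satisfied (the raised-cosine profile is the
special case gamma = 2).

Sessions additionally draw a latent variable that couples reaction time and
accuracy at the session level: under saline a "caution" latent (slower
sessions are more accurate, the classic speed-accuracy trade-off), under
drug a "severity" latent (slower sessions are also less accurate), so the
accuracy-vs-RT correlation flips sign between saline and drug states.

Every injected saccade and every session-level parameter is emitted as
ground truth, so downstream detection and metric stages can be tested by
parameter recovery.  Identical config (including seed) yields identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter
from scipy.special import gammaln

from .io import EyeTrace, TrialMeta, AEPEpochSet, STATES

SUBJECTS = ("Y", "N")


# ---------------------------------------------------------------------------
# main-sequence saccade waveform


@dataclass
class MainSequenceParams:
    """Amplitude-velocity-duration law for synthesised saccades.

    v_max : asymptotic peak velocity (deg/s); a_sat : amplitude saturation
    constant (deg); duration is ``dur_intercept_ms + dur_slope_ms * A``.
    """

    v_max: float = 550.0
    a_sat: float = 5.0
    dur_slope_ms: float = 2.8
    dur_intercept_ms: float = 22.0

    def __post_init__(self):
        if self.v_max <= 0 or self.a_sat <= 0:
            raise ValueError("v_max and a_sat must be positive")

    def peak_velocity(self, amplitude_deg: float) -> float:
        return self.v_max * (1.0 - np.exp(-amplitude_deg / self.a_sat))

    def duration_ms(self, amplitude_deg: float) -> float:
        return self.dur_intercept_ms + self.dur_slope_ms * amplitude_deg


# mean of sin(pi*u)**gamma over u in [0,1]; closed form via Gamma functions
_GAMMA_GRID = np.geomspace(0.02, 80.0, 600)
_MEAN_FRAC = np.exp(
    0.5 * np.log(np.pi)
    + gammaln((_GAMMA_GRID + 1.0) / 2.0)
    - gammaln(_GAMMA_GRID / 2.0 + 1.0)
) / np.pi


def _shape_exponent(c: float) -> float:
    """Solve mean(sin^gamma) = c for gamma (clipped to the tabulated range)."""
    c = float(np.clip(c, _MEAN_FRAC[-1], _MEAN_FRAC[0]))
    # _MEAN_FRAC is decreasing in gamma
    return float(np.interp(c, _MEAN_FRAC[::-1], _GAMMA_GRID[::-1]))


@dataclass
class SaccadeWaveform:
    """Sampled displacement of one synthesised saccade (starting at 0)."""

    dx: np.ndarray
    dy: np.ndarray
    duration_ms: float
    peak_vel_deg_s: float
    amplitude_deg: float
    direction_deg: float
    gamma: float

    @property
    def n(self) -> int:
        return len(self.dx)


def simulate_saccade(
    amplitude_deg: float,
    direction_deg: float,
    ms_params: MainSequenceParams,
    fs_hz: float,
    vel_scale: float = 1.0,
    dur_scale: float = 1.0,
) -> SaccadeWaveform:
    """Synthesise one saccade's displacement waveform.

    Net displacement equals ``amplitude_deg`` (to well within 0.5%), peak
    velocity follows the main sequence scaled by ``vel_scale``, duration
    follows the linear law scaled by ``dur_scale``.
    """
    if amplitude_deg <= 0:
        raise ValueError("saccade amplitude must be positive")
    vp = vel_scale * ms_params.peak_velocity(amplitude_deg)
    dur_ms = dur_scale * ms_params.duration_ms(amplitude_deg)
    dur_s = dur_ms / 1000.0
    # profile peakedness is bounded (empirical saccade velocity profiles are
    # close to raised-cosine, gamma=2); when duration and peak velocity are
    # jointly unsatisfiable the realised peak velocity gives way, and the
    # returned waveform reports the realised value
    gamma = min(_shape_exponent(amplitude_deg / (vp * dur_s)), 3.0)
    # normalised cumulative displacement profile on a fine grid
    u = np.linspace(0.0, 1.0, 801)
    prof = np.sin(np.pi * u) ** gamma
    cum = np.concatenate(([0.0], np.cumsum((prof[1:] + prof[:-1]) / 2.0)))
    cum /= cum[-1]
    # realised peak velocity of the sampled profile (for ground truth)
    vp_real = amplitude_deg / dur_s * prof.max() / np.trapezoid(prof, u)
    n = int(np.ceil(dur_s * fs_hz))
    t_frac = np.minimum(np.arange(1, n + 1) / (fs_hz * dur_s), 1.0)
    frac = np.interp(t_frac, u, cum)
    frac[-1] = 1.0
    rad = np.deg2rad(direction_deg)
    return SaccadeWaveform(
        dx=amplitude_deg * np.cos(rad) * frac,
        dy=amplitude_deg * np.sin(rad) * frac,
        duration_ms=dur_ms,
        peak_vel_deg_s=float(vp_real),
        amplitude_deg=float(amplitude_deg),
        direction_deg=float(direction_deg % 360.0),
        gamma=gamma,
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SubjectProfile:
    """Per-subject baseline habits (inter-individual heterogeneity).

    The free-viewing amplitude distribution is lognormal with the given
    log-mean/log-sd (subject N peaks around 6 deg, subject Y makes mostly
    sub-degree saccades); ``gaze_centers`` are the preferred free-viewing
    loci.  ``aep_noise_uv`` reflects the recording method (scalp vs skull
    electrodes give very different signal-to-noise).
    """

    name: str
    rt_offset_ms: float = 0.0
    vmax_offset: float = 0.0
    pupil_mult: float = 1.0
    drift_mult: float = 1.0
    gain_offset: float = 0.0
    ms_amp_mult: float = 1.0
    fv_amp_logmu: float = 0.0
    fv_amp_logsigma: float = 0.6
    gaze_centers: tuple = (((0.0, 0.0)),)
    aep_noise_uv: float = 10.0
    ket_drift_mult: float = 1.0  # ketamine's fixation-stability effect is
    # heterogeneous across individuals


@dataclass
class StateEffects:
    """Per-state generative parameter set (saline row = baseline).

    All quantities are the *session-mean* level for that state; individual
    sessions scatter around them (see :class:`SessionScatter`).
    """

    anti_acc: float = 0.82
    pro_acc: float = 0.97
    delay_break_p: float = 0.08
    delay_err_p: float = 0.03
    rt_anti_ms: float = 250.0
    rt_pro_ms: float = 185.0
    rt_delay_ms: float = 210.0
    vel_scale: float = 1.0
    dur_scale: float = 1.0
    amp_scale: float = 1.0
    lin_gain: float = 0.92
    lis_gain_x: float = 0.90
    lis_gain_y: float = 0.85
    catchup_base_hz: float = 0.3
    catchup_slope_hz: float = 5.0
    ms_rate_hz: float = 1.3
    ms_amp_deg: float = 0.30
    ms_vel_scale: float = 1.0
    p_down: float = 0.25
    drift_scale: float = 1.0
    pupil_base: float = 1000.0
    pupil_resp: float = 0.25
    pupil_tau_ms: float = 600.0
    fv_rate_hz: float = 2.5
    fv_amp_scale: float = 1.0
    fv_p_down: float = 0.25
    aep_gain: float = 1.0
    deviant_gain: float = 1.25
    sa_sign: float = 1.0  # +1: accuracy rises with RT across sessions
    # (speed-accuracy trade-off); -1: severity latent flips the sign


def default_states() -> dict:
    saline = StateEffects()
    pcp = StateEffects(
        anti_acc=0.62, pro_acc=0.95, delay_break_p=0.30,
        rt_anti_ms=320.0, rt_pro_ms=230.0, rt_delay_ms=265.0,
        vel_scale=0.85, dur_scale=1.18, amp_scale=1.07,
        lin_gain=0.72, lis_gain_x=0.68, lis_gain_y=0.62,
        ms_amp_deg=0.45, ms_vel_scale=1.18, p_down=0.55,
        drift_scale=1.35, pupil_base=850.0, pupil_resp=0.15,
        fv_rate_hz=1.8, fv_amp_scale=1.12, fv_p_down=0.50,
        aep_gain=1.35, deviant_gain=1.05, sa_sign=-1.0,
    )
    ketamine = StateEffects(
        anti_acc=0.68, pro_acc=0.96, delay_break_p=0.16,
        rt_anti_ms=300.0, rt_pro_ms=225.0, rt_delay_ms=250.0,
        vel_scale=0.90, dur_scale=1.08, amp_scale=0.93,
        lin_gain=0.78, lis_gain_x=0.74, lis_gain_y=0.70,
        ms_amp_deg=0.40, ms_vel_scale=1.12, p_down=0.50,
        drift_scale=1.12, pupil_base=900.0, pupil_resp=0.18,
        fv_rate_hz=1.95, fv_amp_scale=0.95, fv_p_down=0.45,
        aep_gain=1.25, deviant_gain=1.12, sa_sign=-1.0,
    )
    return {"saline": saline, "pcp": pcp, "ketamine": ketamine}


def default_subjects() -> dict:
    return {
        "Y": SubjectProfile(
            name="Y",
            fv_amp_logmu=float(np.log(0.7) + 0.36),  # lognormal mode ~0.7 deg
            fv_amp_logsigma=0.6,
            gaze_centers=((0.0, 0.0),),
            aep_noise_uv=20.0,  # scalp electrodes, low SNR
            ket_drift_mult=1.30,
        ),
        "N": SubjectProfile(
            name="N",
            rt_offset_ms=15.0,
            vmax_offset=-25.0,
            pupil_mult=1.15,
            drift_mult=1.15,
            gain_offset=-0.02,
            ms_amp_mult=1.10,
            fv_amp_logmu=float(np.log(6.0) + 0.2),  # lognormal mode ~6 deg
            fv_amp_logsigma=0.45,
            gaze_centers=((0.0, 0.0), (-6.0, -5.0), (6.0, -5.0)),
            aep_noise_uv=8.0,  # skull electrodes, high SNR
            ket_drift_mult=0.90,
        ),
    }


@dataclass
class SessionScatter:
    """Session-to-session SDs around state means (realistic day-to-day
    variability; the latent-coupling terms implement the accuracy-RT
    correlation)."""

    acc_logit: float = 0.25
    rt_ms: float = 12.0
    vel: float = 0.04
    dur: float = 0.05
    amp: float = 0.03
    gain: float = 0.04
    ms_amp_rel: float = 0.12
    ms_vel: float = 0.05
    p_down: float = 0.05
    drift_rel: float = 0.08
    pupil_base: float = 40.0
    pupil_resp: float = 0.025
    fv_rate: float = 0.25
    fv_amp_rel: float = 0.08
    aep_gain: float = 0.06
    latent_rt_ms: float = 22.0
    latent_acc_beta: float = 0.5


@dataclass
class TrialCounts:
    anti: int = 20
    pro: int = 16
    delayed: int = 16
    linear: int = 3
    lissajous: int = 3
    fixation: int = 5
    freeview: int = 2


@dataclass
class AEPParams:
    """Generative ERP model: three Gaussian components (P50, N100, P200)
    on a -100..400 ms epoch, scaled multiplicatively by tone intensity,
    tone pitch, injection state and (for oddballs) a deviant gain, plus
    1/f-shaped noise and a random per-epoch DC offset."""

    fs_hz: float = 500.0
    t_pre_ms: float = 100.0
    t_post_ms: float = 400.0
    # (amplitude uV, centre ms, width ms)
    components: tuple = ((2.0, 50.0, 12.0), (-4.0, 100.0, 20.0), (4.5, 185.0, 28.0))
    intensity_gains: tuple = ((60, 0.6), (80, 1.0))
    pitch_gains: tuple = ((1200, 0.75), (1500, 1.0))
    dc_sd_uv: float = 3.0

    @property
    def t_ms(self) -> np.ndarray:
        dt = 1000.0 / self.fs_hz
        return np.arange(-self.t_pre_ms, self.t_post_ms + dt / 2, dt)


@dataclass
class GeneratorConfig:
    """Full study-condition description for the synthetic generator.

    Defaults are the study conditions used throughout: two subjects, three
    states, 40 sessions per state per subject, 500 Hz eye tracking with
    0.015 deg RMS measurement noise.
    """

    seed: int = 0
    fs_hz: float = 500.0
    sessions_per_state: int = 40
    tasks: tuple = (
        "anti_saccade", "pro_saccade", "delayed_saccade", "linear_pursuit",
        "lissajous_pursuit", "fixation", "free_viewing",
    )
    trials: TrialCounts = field(default_factory=TrialCounts)
    subjects: dict = field(default_factory=default_subjects)
    states: dict = field(default_factory=default_states)
    main_seq: MainSequenceParams = field(default_factory=MainSequenceParams)
    scatter: SessionScatter = field(default_factory=SessionScatter)
    aep: AEPParams = field(default_factory=AEPParams)
    # task geometry / timing
    target_ecc_deg: float = 10.0
    fix_dur_s: float = 3.0
    linear_dur_s: float = 8.0
    linear_speed_deg_s: float = 10.0
    linear_span_deg: float = 8.0
    lis_dur_s: float = 10.0
    lis_ax_deg: float = 8.0
    lis_ay_deg: float = 8.0
    lis_fx_hz: float = 0.2
    lis_fy_hz: float = 0.3
    fv_dur_s: float = 15.0
    drift_base_deg_s: float = 1.0
    # noise model
    noise_deg: float = 0.015
    pupil_noise: float = 3.0
    blink_prob: float = 0.05
    dropout_prob: float = 0.1

    def __post_init__(self):
        for st, eff in self.states.items():
            if st not in STATES:
                raise ValueError(f"unknown state {st!r}")
            for f in ("anti_acc", "pro_acc", "delay_break_p", "p_down", "fv_p_down"):
                if not 0.0 <= getattr(eff, f) <= 1.0:
                    raise ValueError(f"{st}.{f} must be a probability")
            for f in ("vel_scale", "dur_scale", "amp_scale", "aep_gain"):
                if getattr(eff, f) <= 0:
                    raise ValueError(f"{st}.{f} must be positive")
        unknown = set(self.tasks) - {
            "anti_saccade", "pro_saccade", "delayed_saccade", "linear_pursuit",
            "lissajous_pursuit", "fixation", "free_viewing",
        }
        if unknown:
            raise ValueError(f"unknown task(s): {sorted(unknown)}")

    def noiseless(self) -> "GeneratorConfig":
        """Copy with measurement noise, blinks and ocular drift disabled."""
        cfg = dataclasses.replace(
            self, noise_deg=0.0, pupil_noise=0.0, blink_prob=0.0, dropout_prob=0.0,
            drift_base_deg_s=0.0,
        )
        cfg.states = {k: replace(v) for k, v in self.states.items()}
        cfg.subjects = {k: replace(v) for k, v in self.subjects.items()}
        return cfg

    def null_effects(self) -> "GeneratorConfig":
        """Copy in which every state behaves like saline (no drug effect)."""
        cfg = dataclasses.replace(self)
        base = self.states["saline"]
        cfg.states = {k: replace(base) for k in self.states}
        cfg.subjects = {k: replace(v) for k, v in self.subjects.items()}
        return cfg


# ---------------------------------------------------------------------------
# session-level parameter draws


@dataclass
class SessionParams:
    anti_acc: float
    pro_acc: float
    delay_break_p: float
    delay_err_p: float
    rt_anti: float
    rt_pro: float
    rt_delay: float
    vel_scale: float
    dur_scale: float
    amp_scale: float
    lin_gain: float
    lis_gain_x: float
    lis_gain_y: float
    catchup_base: float
    catchup_slope: float
    ms_rate: float
    ms_amp_deg: float
    ms_vel_scale: float
    p_down: float
    drift_v: float
    pupil_b: float
    pupil_r: float
    pupil_tau: float
    fv_rate: float
    fv_amp_logmu: float
    fv_amp_logsigma: float
    fv_p_down: float
    latent_z: float


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_session_params(
    rng: np.random.Generator, cfg: GeneratorConfig, subj: SubjectProfile,
    eff: StateEffects,
) -> SessionParams:
    sc = cfg.scatter
    z = rng.normal()
    # latent couples RT (always positively) and accuracy (sign per state)
    acc_logit = (
        _logit(eff.anti_acc)
        + eff.sa_sign * sc.latent_acc_beta * z
        + rng.normal(0, sc.acc_logit)
    )
    rt_anti = (
        eff.rt_anti_ms + subj.rt_offset_ms + sc.latent_rt_ms * z
        + rng.normal(0, sc.rt_ms)
    )
    drift_mult = subj.drift_mult * (
        subj.ket_drift_mult if eff is not None and _is_ketamine(eff) else 1.0
    )
    return SessionParams(
        anti_acc=float(np.clip(_expit(acc_logit), 0.02, 0.995)),
        pro_acc=float(np.clip(_expit(_logit(eff.pro_acc) + rng.normal(0, sc.acc_logit)), 0.02, 0.995)),
        delay_break_p=float(np.clip(
            _expit(_logit(max(eff.delay_break_p, 1e-3)) + rng.normal(0, sc.acc_logit)),
            0.0, 0.9,
        )),
        delay_err_p=eff.delay_err_p,
        rt_anti=float(np.clip(rt_anti, 120, 500)),
        rt_pro=float(np.clip(eff.rt_pro_ms + subj.rt_offset_ms + rng.normal(0, sc.rt_ms), 100, 450)),
        rt_delay=float(np.clip(eff.rt_delay_ms + subj.rt_offset_ms + rng.normal(0, sc.rt_ms), 100, 450)),
        vel_scale=float(max(eff.vel_scale + rng.normal(0, sc.vel), 0.3)),
        dur_scale=float(max(eff.dur_scale + rng.normal(0, sc.dur), 0.5)),
        amp_scale=float(max(eff.amp_scale + rng.normal(0, sc.amp), 0.5)),
        lin_gain=float(np.clip(eff.lin_gain + subj.gain_offset + rng.normal(0, sc.gain), 0.05, 1.15)),
        lis_gain_x=float(np.clip(eff.lis_gain_x + subj.gain_offset + rng.normal(0, sc.gain), 0.05, 1.15)),
        lis_gain_y=float(np.clip(eff.lis_gain_y + subj.gain_offset + rng.normal(0, sc.gain), 0.05, 1.15)),
        catchup_base=eff.catchup_base_hz,
        catchup_slope=eff.catchup_slope_hz,
        ms_rate=float(max(eff.ms_rate_hz + rng.normal(0, 0.15), 0.4)),
        ms_amp_deg=float(
            eff.ms_amp_deg * subj.ms_amp_mult * max(1.0 + rng.normal(0, sc.ms_amp_rel), 0.4)
        ),
        ms_vel_scale=float(max(eff.ms_vel_scale + rng.normal(0, sc.ms_vel), 0.5)),
        p_down=float(np.clip(eff.p_down + rng.normal(0, sc.p_down), 0.0, 1.0)),
        drift_v=float(
            cfg.drift_base_deg_s * eff.drift_scale * drift_mult
            * max(1.0 + rng.normal(0, sc.drift_rel), 0.3)
        ),
        pupil_b=float(max(eff.pupil_base * subj.pupil_mult + rng.normal(0, sc.pupil_base), 200)),
        pupil_r=float(np.clip(eff.pupil_resp + rng.normal(0, sc.pupil_resp), 0.02, 0.6)),
        pupil_tau=eff.pupil_tau_ms,
        fv_rate=float(max(eff.fv_rate_hz + rng.normal(0, sc.fv_rate), 0.5)),
        fv_amp_logmu=float(
            subj.fv_amp_logmu
            + np.log(eff.fv_amp_scale * max(1.0 + rng.normal(0, sc.fv_amp_rel), 0.4))
        ),
        fv_amp_logsigma=subj.fv_amp_logsigma,
        fv_p_down=float(np.clip(eff.fv_p_down + rng.normal(0, sc.p_down), 0.0, 1.0)),
        latent_z=float(z),
    )


def _is_ketamine(eff: StateEffects) -> bool:
    # subject-dependent ketamine heterogeneity is keyed off the state dict
    # at session assembly; this placeholder is replaced there.
    return getattr(eff, "_is_ketamine", False)


# ---------------------------------------------------------------------------
# building blocks


def _drift(rng, n, fs, sigma_v, tau_v=0.12, tau_p=1.0):
    """Smooth zero-mean ocular drift: AR(1) velocity (OU with time constant
    tau_v, stationary SD sigma_v) integrated through a leaky integrator
    (recentring time constant tau_p)."""
    if sigma_v <= 0 or n == 0:
        return np.zeros(n)
    dt = 1.0 / fs
    a_v = 1.0 - dt / tau_v
    innov = rng.normal(0.0, sigma_v * np.sqrt(1.0 - a_v**2), size=n)
    v = lfilter([1.0], [1.0, -a_v], innov)
    a_p = 1.0 - dt / tau_p
    return lfilter([dt], [1.0, -a_p], v)


def _inject(x, y, i0, wf: SaccadeWaveform):
    """Add a saccade displacement starting after sample i0 (position begins
    moving between i0 and i0+1)."""
    n = len(x)
    m = min(wf.n, n - 1 - i0)
    if m <= 0:
        return
    x[i0 + 1 : i0 + 1 + m] += wf.dx[:m]
    y[i0 + 1 : i0 + 1 + m] += wf.dy[:m]
    if i0 + 1 + m < n:
        x[i0 + 1 + m :] += wf.dx[m - 1]
        y[i0 + 1 + m :] += wf.dy[m - 1]


def _gt_event(t_ms_onset, wf: SaccadeWaveform, micro_max=2.0):
    return {
        "onset_ms": float(t_ms_onset),
        "amplitude_deg": wf.amplitude_deg,
        "direction_deg": wf.direction_deg,
        "duration_ms": wf.duration_ms,
        "peak_vel_deg_s": wf.peak_vel_deg_s,
        "avg_vel_deg_s": wf.amplitude_deg / (wf.duration_ms / 1000.0),
        "is_microsaccade": wf.amplitude_deg < micro_max,
    }


def _angle_from_horizontal(direction_deg):
    f = direction_deg % 180.0
    return min(f, 180.0 - f)


def _finalize(rng, cfg, x, y, pupil):
    """Apply measurement noise, short dropouts and blinks in place."""
    n = len(x)
    if cfg.noise_deg > 0:
        x += rng.normal(0, cfg.noise_deg, n)
        y += rng.normal(0, cfg.noise_deg, n)
    if cfg.pupil_noise > 0:
        pupil += rng.normal(0, cfg.pupil_noise, n)
    dt_ms = 1000.0 / cfg.fs_hz
    if cfg.dropout_prob > 0 and rng.random() < cfg.dropout_prob and n > 50:
        # short tracker dropout, interpolable downstream
        ln = int(rng.uniform(10, 40) / dt_ms)
        s = rng.integers(10, n - ln - 10)
        x[s : s + ln] = np.nan
        y[s : s + ln] = np.nan
    if cfg.blink_prob > 0 and rng.random() < cfg.blink_prob and n > 300:
        ln = int(rng.uniform(80, 200) / dt_ms)
        s = rng.integers(10, n - ln - 10)
        x[s : s + ln] = np.nan
        y[s : s + ln] = np.nan
        pupil[s : s + ln] = np.nan


def _ms_amp_draw(rng, mu_deg, sigma=0.4, lo=0.18, hi=1.8):
    return float(np.clip(rng.lognormal(np.log(mu_deg), sigma), lo, hi))


def _ms_direction(rng, p_down, kappa=4.0):
    """Microsaccade direction: downward von Mises component with prob
    p_down, else uniform."""
    if rng.random() < p_down:
        return float(np.degrees(rng.vonmises(-np.pi / 2.0, kappa)) % 360.0)
    return float(rng.uniform(0.0, 360.0))


# ---------------------------------------------------------------------------
# per-task trial builders


def _meta(cfg, subj, state, session_id, task, trial_id, cue="none", tdir=np.nan):
    return TrialMeta(
        session_id=session_id, subject=subj.name, state=state, task=task,
        trial_id=trial_id, cue=cue, target_direction_deg=tdir,
    )


def _sim_instructed_saccade_trial(
    rng, cfg: GeneratorConfig, subj, p: SessionParams, kind: str
):
    """One anti-, pro- or delayed-saccade trial.

    Returns (t_ms, x, y, pupil, tx, ty, events, gt) with gt carrying the
    injected events and the trial outcome.
    """
    fs = cfg.fs_hz
    dt = 1000.0 / fs
    ms = replace(cfg.main_seq, v_max=cfg.main_seq.v_max + subj.vmax_offset)
    side = 0.0 if rng.random() < 0.5 else 180.0
    ecc = cfg.target_ecc_deg

    if kind == "delayed":
        target_on, go_ms = 500.0, 1100.0
        acc_dir = 1.0  # delayed saccades go toward the target
        rt_mean = p.rt_delay
    else:
        target_on = go_ms = 800.0
        rt_mean = p.rt_anti if kind == "anti" else p.rt_pro
    cue_ms = 300.0

    gt_events = []
    events = {"fixation_on": 0, "cue_on": int(round(cue_ms / dt))}

    # optional fixational microsaccade before the target appears
    pre_micro = None
    if rng.random() < 0.3:
        onset = rng.uniform(80.0, target_on - 180.0)
        wf = simulate_saccade(
            _ms_amp_draw(rng, p.ms_amp_deg, hi=0.8),
            _ms_direction(rng, p.p_down),
            ms, fs, vel_scale=p.ms_vel_scale,
            dur_scale=float(rng.lognormal(0.0, 0.10)),
        )
        pre_micro = (int(round(onset / dt)), wf)

    broke = False
    responded = True
    correct = True
    rt_draw = float(np.clip(rng.normal(rt_mean, 45.0), 90.0, 600.0))

    if kind == "delayed" and rng.random() < p.delay_break_p:
        broke = True
        responded = False
        correct = False
        break_ms = target_on + rng.uniform(80.0, go_ms - target_on - 60.0)
        resp_dir = side  # reflexive saccade toward the target
        resp_onset_ms = break_ms
        has_go = False
    else:
        has_go = True
        if kind == "delayed":
            correct = rng.random() >= p.delay_err_p
            resp_dir = side if correct else (side + 180.0) % 360.0
        elif kind == "anti":
            correct = rng.random() < p.anti_acc
            resp_dir = (side + 180.0) % 360.0 if correct else side
        else:  # pro
            correct = rng.random() < p.pro_acc
            resp_dir = side if correct else (side + 180.0) % 360.0
        if rng.random() < 0.02:
            responded = False
            correct = False
        resp_onset_ms = go_ms + rt_draw

    resp_wf = None
    if responded or broke:
        amp = float(max(ecc * p.amp_scale * (1.0 + rng.normal(0, 0.05)), 1.0))
        direction = resp_dir + rng.normal(0, 6.0)
        resp_wf = simulate_saccade(
            amp, direction, ms, fs, vel_scale=p.vel_scale,
            dur_scale=p.dur_scale * float(rng.lognormal(0.0, 0.08)),
        )
        end_ms = resp_onset_ms + resp_wf.duration_ms + 250.0
    else:
        end_ms = go_ms + 700.0

    n = int(round(end_ms / dt)) + 1
    t = np.arange(n) * dt
    x = _drift(rng, n, fs, p.drift_v)
    y = _drift(rng, n, fs, p.drift_v)
    tx = np.zeros(n)
    ty = np.zeros(n)
    ton_idx = int(round(target_on / dt))
    go_idx = int(round(go_ms / dt))
    tx[ton_idx:] = ecc * np.cos(np.deg2rad(side))
    events["target_on"] = ton_idx
    # for anti/pro the target onset IS the go signal (same sample); a
    # separate marker exists only in the delayed task
    if has_go and kind == "delayed":
        events["go_signal"] = go_idx
    events["trial_end"] = n - 1

    if pre_micro is not None:
        i0, wf = pre_micro
        _inject(x, y, i0, wf)
        gt_events.append(_gt_event(t[i0], wf))
    if resp_wf is not None:
        i0 = int(round(resp_onset_ms / dt))
        _inject(x, y, i0, resp_wf)
        gt_events.append(_gt_event(t[i0], resp_wf))

    pupil = np.full(n, p.pupil_b)
    _finalize(rng, cfg, x, y, pupil)
    rt_gt = (int(round(resp_onset_ms / dt)) - go_idx) * dt \
        if (responded and has_go) else np.nan
    gt = {
        "events": gt_events,
        "correct": bool(correct),
        "responded": bool(responded and has_go),
        "broke": bool(broke),
        "rt_ms": float(rt_gt) if np.isfinite(rt_gt) else None,
        "resp_amp": resp_wf.amplitude_deg if (resp_wf and responded) else None,
        "resp_dur": resp_wf.duration_ms if (resp_wf and responded) else None,
        "resp_vel": (
            resp_wf.amplitude_deg / (resp_wf.duration_ms / 1000.0)
            if (resp_wf and responded) else None
        ),
        "side_deg": side,
    }
    return t, x, y, pupil, tx, ty, events, gt


def _triangle_pos(d, span):
    """Triangular sweep through [-span, span] starting at 0, rising."""
    m = np.mod(d + span, 4.0 * span)
    return np.where(m < 2.0 * span, m - span, 3.0 * span - m)


def _sim_linear_pursuit_trial(rng, cfg, subj, p: SessionParams):
    fs = cfg.fs_hz
    dt = 1000.0 / fs
    ms = replace(cfg.main_seq, v_max=cfg.main_seq.v_max + subj.vmax_offset)
    n = int(round(cfg.linear_dur_s * fs)) + 1
    t = np.arange(n) * dt
    t0_ms = 200.0
    i0 = int(round(t0_ms / dt))
    sgn = 1.0 if rng.random() < 0.5 else -1.0
    d = sgn * cfg.linear_speed_deg_s * (t - t0_ms) / 1000.0
    tx = np.where(t >= t0_ms, _triangle_pos(d, cfg.linear_span_deg), 0.0)
    ty = np.zeros(n)

    g = p.lin_gain
    x = g * tx  # smooth pursuit component
    y = np.zeros(n)

    gt_events = []
    rate = p.catchup_base + p.catchup_slope * max(1.0 - g, 0.0)
    t_next = t0_ms / 1000.0 + 0.3 + rng.exponential(1.0 / rate)
    while t_next < cfg.linear_dur_s - 0.15:
        idx = int(round(t_next * fs))
        # x already contains earlier catch-up displacements (injected in place)
        err = tx[idx] - x[idx]
        if abs(err) >= 0.3:
            wf = simulate_saccade(
                abs(err), 0.0 if err > 0 else 180.0, ms, fs,
                vel_scale=p.vel_scale,
                dur_scale=p.dur_scale * float(rng.lognormal(0.0, 0.08)),
            )
            _inject(x, y, idx, wf)
            gt_events.append(_gt_event(t[idx], wf))
        t_next += 0.15 + rng.exponential(1.0 / rate)

    x += _drift(rng, n, fs, 0.4 * p.drift_v)
    y += _drift(rng, n, fs, 0.4 * p.drift_v)
    pupil = np.full(n, p.pupil_b)
    events = {"fixation_on": 0, "target_on": i0, "trial_end": n - 1}
    _finalize(rng, cfg, x, y, pupil)
    analysis_s = cfg.linear_dur_s - (t0_ms + 200.0) / 1000.0
    n_in = sum(1 for e in gt_events if e["onset_ms"] >= t0_ms + 200.0)
    gt = {"events": gt_events, "gain": g, "sacc_rate": n_in / analysis_s}
    return t, x, y, pupil, tx, ty, events, gt


def _sim_lissajous_trial(rng, cfg, subj, p: SessionParams):
    fs = cfg.fs_hz
    dt = 1000.0 / fs
    ms = replace(cfg.main_seq, v_max=cfg.main_seq.v_max + subj.vmax_offset)
    n = int(round(cfg.lis_dur_s * fs)) + 1
    t = np.arange(n) * dt
    t0_ms = 200.0
    i0 = int(round(t0_ms / dt))
    ts = np.maximum(t - t0_ms, 0.0) / 1000.0
    wx = 2.0 * np.pi * cfg.lis_fx_hz
    wy = 2.0 * np.pi * cfg.lis_fy_hz
    tx = cfg.lis_ax_deg * np.sin(wx * ts)
    ty = cfg.lis_ay_deg * np.sin(wy * ts)

    gx, gy = p.lis_gain_x, p.lis_gain_y
    phi = 0.08  # small pursuit phase lag (rad)
    x = gx * cfg.lis_ax_deg * np.sin(np.maximum(wx * ts - phi, 0.0) * (ts > 0))
    y = gy * cfg.lis_ay_deg * np.sin(np.maximum(wy * ts - phi, 0.0) * (ts > 0))

    gt_events = []
    rate = p.catchup_base + p.catchup_slope * max(1.0 - (gx + gy) / 2.0, 0.0)
    t_next = t0_ms / 1000.0 + 0.3 + rng.exponential(1.0 / rate)
    while t_next < cfg.lis_dur_s - 0.15:
        idx = int(round(t_next * fs))
        ex = tx[idx] - x[idx]
        ey = ty[idx] - y[idx]
        amp = float(np.hypot(ex, ey))
        if amp >= 0.3:
            wf = simulate_saccade(
                amp, float(np.degrees(np.arctan2(ey, ex))), ms, fs,
                vel_scale=p.vel_scale,
                dur_scale=p.dur_scale * float(rng.lognormal(0.0, 0.08)),
            )
            _inject(x, y, idx, wf)
            gt_events.append(_gt_event(t[idx], wf))
        t_next += 0.15 + rng.exponential(1.0 / rate)

    x += _drift(rng, n, fs, 0.4 * p.drift_v)
    y += _drift(rng, n, fs, 0.4 * p.drift_v)
    pupil = np.full(n, p.pupil_b)
    events = {"fixation_on": 0, "target_on": i0, "trial_end": n - 1}
    _finalize(rng, cfg, x, y, pupil)
    analysis_s = cfg.lis_dur_s - (t0_ms + 200.0) / 1000.0
    n_in = sum(1 for e in gt_events if e["onset_ms"] >= t0_ms + 200.0)
    gt = {
        "events": gt_events, "gain_x": gx, "gain_y": gy,
        "sacc_rate": n_in / analysis_s,
    }
    return t, x, y, pupil, tx, ty, events, gt


def _sim_fixation_trial(rng, cfg, subj, p: SessionParams):
    fs = cfg.fs_hz
    dt = 1000.0 / fs
    ms = replace(cfg.main_seq, v_max=cfg.main_seq.v_max + subj.vmax_offset)
    n = int(round(cfg.fix_dur_s * fs)) + 1
    t = np.arange(n) * dt
    x = _drift(rng, n, fs, p.drift_v)
    y = _drift(rng, n, fs, p.drift_v)

    gt_events = []
    t_next = 0.25 + rng.exponential(1.0 / p.ms_rate)
    while t_next < cfg.fix_dur_s - 0.1:
        idx = int(round(t_next * fs))
        wf = simulate_saccade(
            _ms_amp_draw(rng, p.ms_amp_deg),
            _ms_direction(rng, p.p_down),
            ms, fs, vel_scale=p.ms_vel_scale,
            dur_scale=float(rng.lognormal(0.0, 0.10)),
        )
        _inject(x, y, idx, wf)
        gt_events.append(_gt_event(t[idx], wf))
        t_next += 0.15 + rng.exponential(1.0 / p.ms_rate)

    # pupil: slow light-adaptation-like constriction from baseline
    tau = p.pupil_tau
    pupil_clean = p.pupil_b * (1.0 - p.pupil_r * (1.0 - np.exp(-t / tau)))
    pupil = pupil_clean.copy()

    # analytic pupil ground truth over the same measurement windows
    first500 = t < 500.0
    first200 = t < 200.0
    last1000 = t >= (t[-1] - 1000.0)
    gt_pupil_size = float(pupil_clean[first500].mean())
    gt_baseline = float(pupil_clean[first200].mean())
    gt_resp = float(pupil_clean[last1000].mean() - gt_baseline)

    # realised fixation-stability ground truth (closed form on the generated
    # gaze, before measurement noise)
    sx = np.std(x, ddof=1)
    sy = np.std(y, ddof=1)
    rho = 0.0
    if sx > 0 and sy > 0:
        rho = float(np.corrcoef(x, y)[0, 1])
    bcea = 2.0 * (-np.log(1.0 - 0.68)) * np.pi * sx * sy * np.sqrt(1.0 - rho**2)

    tx = np.zeros(n)
    ty = np.zeros(n)
    events = {"fixation_on": 0, "trial_end": n - 1}
    _finalize(rng, cfg, x, y, pupil)
    gt = {
        "events": gt_events,
        "pupil_size": gt_pupil_size,
        "pupil_response": gt_resp,
        "bcea_deg2": float(bcea),
    }
    return t, x, y, pupil, tx, ty, events, gt


def _sim_freeview_trial(rng, cfg, subj, p: SessionParams):
    fs = cfg.fs_hz
    dt = 1000.0 / fs
    ms = replace(cfg.main_seq, v_max=cfg.main_seq.v_max + subj.vmax_offset)
    n = int(round(cfg.fv_dur_s * fs)) + 1
    t = np.arange(n) * dt
    x = _drift(rng, n, fs, p.drift_v)
    y = _drift(rng, n, fs, p.drift_v)

    centers = np.asarray(subj.gaze_centers, dtype=float)
    cur = centers[rng.integers(len(centers))] + rng.normal(0, 1.0, 2)
    x += cur[0]
    y += cur[1]

    gt_events = []
    t_next = 0.2 + rng.exponential(1.0 / p.fv_rate)
    while t_next < cfg.fv_dur_s - 0.1:
        idx = int(round(t_next * fs))
        amp = float(np.clip(
            rng.lognormal(p.fv_amp_logmu, p.fv_amp_logsigma), 0.3, 14.0
        ))
        if rng.random() < p.fv_p_down:
            direction = float(np.degrees(rng.vonmises(-np.pi / 2.0, 2.0)) % 360.0)
        else:
            direction = float(rng.uniform(0.0, 360.0))
        rad = np.deg2rad(direction)
        end = cur + amp * np.array([np.cos(rad), np.sin(rad)])
        if np.hypot(*end) > 11.0:
            # refixate toward one of the subject's habitual gaze loci
            c = centers[rng.integers(len(centers))] + rng.normal(0, 1.5, 2)
            vec = c - cur
            dist = float(np.hypot(*vec))
            if dist < 0.3:
                t_next += 0.12 + rng.exponential(1.0 / p.fv_rate)
                continue
            direction = float(np.degrees(np.arctan2(vec[1], vec[0])) % 360.0)
            amp = min(amp, dist)
        wf = simulate_saccade(
            amp, direction, ms, fs, vel_scale=p.vel_scale,
            dur_scale=float(rng.lognormal(0.0, 0.08)),
        )
        _inject(x, y, idx, wf)
        rad = np.deg2rad(direction)
        cur = cur + amp * np.array([np.cos(rad), np.sin(rad)])
        gt_events.append(_gt_event(t[idx], wf))
        t_next += 0.12 + rng.exponential(1.0 / p.fv_rate)

    tx = np.zeros(n)
    ty = np.zeros(n)
    pupil = np.full(n, p.pupil_b)
    events = {"fixation_on": 0, "trial_end": n - 1}
    _finalize(rng, cfg, x, y, pupil)
    gt = {"events": gt_events, "rate": len(gt_events) / cfg.fv_dur_s}
    return t, x, y, pupil, tx, ty, events, gt


# ---------------------------------------------------------------------------
# session assembly


@dataclass
class SessionData:
    """One generated session: trials plus the ground-truth manifest."""

    subject: str
    state: str
    session_id: str
    trials: list
    ground_truth: dict


def _mean(vals):
    vals = [v for v in vals if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def simulate_session(
    cfg: GeneratorConfig, subject: str, state: str, session_idx: int
) -> SessionData:
    """Generate all trials of one session plus ground truth.

    Seeding is hierarchical: (cfg.seed, subject index, state index,
    session index), so any session can be regenerated independently and the
    whole study is reproducible byte-for-byte.
    """
    if subject not in cfg.subjects:
        raise ValueError(f"unknown subject {subject!r}")
    if state not in cfg.states:
        raise ValueError(f"unknown state {state!r}")
    subj = cfg.subjects[subject]
    eff = replace(cfg.states[state])
    eff._is_ketamine = state == "ketamine"
    s_idx = list(cfg.subjects).index(subject)
    st_idx = list(cfg.states).index(state)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, s_idx, st_idx, session_idx])
    )
    p = _draw_session_params(rng, cfg, subj, eff)
    session_id = f"{subject}_{state}_{session_idx:03d}"

    trials = []
    feats: dict = {}
    trial_id = 0

    def add(task, builder, cue="none", count=1):
        nonlocal trial_id
        out = []
        for _ in range(count):
            t, x, y, pupil, tx, ty, events, gt = builder()
            trace = EyeTrace(
                t_ms=t, x_deg=x, y_deg=y, pupil_au=pupil,
                target_x_deg=tx, target_y_deg=ty, fs_hz=cfg.fs_hz, events=events,
            )
            meta = _meta(cfg, subj, state, session_id, task, trial_id, cue=cue)
            meta.ground_truth = gt
            trials.append((trace, meta))
            out.append(gt)
            trial_id += 1
        return out

    for kind, task, cue, count, acc_key in (
        ("anti", "anti_saccade", "anti", cfg.trials.anti, "anti"),
        ("pro", "pro_saccade", "pro", cfg.trials.pro, "pro"),
        ("delayed", "delayed_saccade", "pro", cfg.trials.delayed, "delay"),
    ):
        if task not in cfg.tasks:
            continue
        gts = add(
            task,
            lambda kind=kind: _sim_instructed_saccade_trial(rng, cfg, subj, p, kind),
            cue=cue, count=count,
        )
        feats[f"{acc_key}_accuracy"] = _mean([g["correct"] for g in gts])
        feats[f"{acc_key}_rt_ms"] = _mean([g["rt_ms"] for g in gts])
        feats[f"{acc_key}_sacc_vel"] = _mean([g["resp_vel"] for g in gts])
        feats[f"{acc_key}_sacc_dur"] = _mean([g["resp_dur"] for g in gts])
        feats[f"{acc_key}_sacc_amp"] = _mean([g["resp_amp"] for g in gts])

    if "linear_pursuit" in cfg.tasks:
        gts = add(
            "linear_pursuit",
            lambda: _sim_linear_pursuit_trial(rng, cfg, subj, p),
            count=cfg.trials.linear,
        )
        feats["lin_gain"] = _mean([g["gain"] for g in gts])
        feats["lin_sacc_rate"] = _mean([g["sacc_rate"] for g in gts])

    if "lissajous_pursuit" in cfg.tasks:
        gts = add(
            "lissajous_pursuit",
            lambda: _sim_lissajous_trial(rng, cfg, subj, p),
            count=cfg.trials.lissajous,
        )
        feats["lis_gain_x"] = _mean([g["gain_x"] for g in gts])
        feats["lis_gain_y"] = _mean([g["gain_y"] for g in gts])
        feats["lis_sacc_rate"] = _mean([g["sacc_rate"] for g in gts])

    if "fixation" in cfg.tasks:
        gts = add(
            "fixation",
            lambda: _sim_fixation_trial(rng, cfg, subj, p),
            count=cfg.trials.fixation,
        )
        evs = [e for g in gts for e in g["events"]]
        feats["ms_angle_deg"] = _mean(
            [_angle_from_horizontal(e["direction_deg"]) for e in evs]
        )
        feats["ms_vel"] = _mean([e["avg_vel_deg_s"] for e in evs])
        feats["ms_dur"] = _mean([e["duration_ms"] for e in evs])
        feats["ms_amp"] = _mean([e["amplitude_deg"] for e in evs])
        feats["ms_down_frac"] = _mean(
            [np.sin(np.deg2rad(e["direction_deg"])) < 0 for e in evs]
        )
        feats["bcea_deg2"] = _mean([g["bcea_deg2"] for g in gts])
        feats["pupil_size"] = _mean([g["pupil_size"] for g in gts])
        feats["pupil_response"] = _mean([g["pupil_response"] for g in gts])

    if "free_viewing" in cfg.tasks:
        gts = add(
            "free_viewing",
            lambda: _sim_freeview_trial(rng, cfg, subj, p),
            count=cfg.trials.freeview,
        )
        evs = [e for g in gts for e in g["events"]]
        feats["fv_sacc_rate"] = _mean([g["rate"] for g in gts])
        feats["fv_sacc_amp_med"] = (
            float(np.median([e["amplitude_deg"] for e in evs])) if evs else float("nan")
        )
        feats["fv_angle_deg"] = _mean(
            [_angle_from_horizontal(e["direction_deg"]) for e in evs]
        )

    gt = {
        "features": feats,
        "params": {
            f.name: getattr(p, f.name) for f in dataclasses.fields(SessionParams)
        },
    }
    return SessionData(
        subject=subject, state=state, session_id=session_id,
        trials=trials, ground_truth=gt,
    )


def simulate_study(cfg: GeneratorConfig) -> list[SessionData]:
    """All sessions: every subject x state x sessions_per_state."""
    out = []
    for subject in cfg.subjects:
        for state in cfg.states:
            for i in range(cfg.sessions_per_state):
                out.append(simulate_session(cfg, subject, state, i))
    return out


# ---------------------------------------------------------------------------
# auditory oddball EEG


def aep_template(t_ms: np.ndarray, params: AEPParams) -> np.ndarray:
    """Noise-free unit-gain evoked-potential template (microvolts)."""
    t_ms = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t_ms)
    for amp, mu, sd in params.components:
        out += amp * np.exp(-0.5 * ((t_ms - mu) / sd) ** 2)
    return out


def _pink_noise(rng, n_epochs, n_t, sd):
    """1/f-amplitude-shaped Gaussian noise, per-epoch SD = sd."""
    if sd <= 0:
        return np.zeros((n_epochs, n_t))
    nf = n_t // 2 + 1
    f = np.arange(nf, dtype=float)
    shape = np.zeros(nf)
    shape[1:] = f[1:] ** -0.5
    spec = (rng.normal(size=(n_epochs, nf)) + 1j * rng.normal(size=(n_epochs, nf))) * shape
    x = np.fft.irfft(spec, n=n_t, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * sd


def simulate_aep_epochs(
    cfg: GeneratorConfig,
    state: str,
    tone_db: int,
    tone_hz: int,
    role: str,
    n_epochs: int,
    subject: str = "N",
    block: str = "A",
    rng: np.random.Generator | None = None,
    noise_sd_uv: float | None = None,
) -> AEPEpochSet:
    """Simulate stimulus-locked epochs for one tone condition.

    Each epoch is the Gaussian-component ERP template scaled by intensity,
    pitch, state and (for deviants) deviant gain, plus 1/f noise and a
    random DC offset; the pre-stimulus window is mean-zero in expectation.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    ap = cfg.aep
    igain = dict(ap.intensity_gains)
    pgain = dict(ap.pitch_gains)
    if tone_db not in igain or tone_hz not in pgain:
        raise ValueError(f"unknown tone attributes ({tone_db} dB, {tone_hz} Hz)")
    if state not in cfg.states:
        raise ValueError(f"unknown state {state!r}")
    eff = cfg.states[state]
    gain = igain[tone_db] * pgain[tone_hz] * eff.aep_gain
    if role == "deviant":
        gain *= eff.deviant_gain
    elif role != "standard":
        raise ValueError(f"unknown role {role!r}")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([
                cfg.seed, 7919, list(cfg.states).index(state),
                list(cfg.subjects).index(subject),
                tone_db, tone_hz, int(role == "deviant"), ord(block[0]),
            ])
        )
    t = ap.t_ms
    sd = cfg.subjects[subject].aep_noise_uv if noise_sd_uv is None else noise_sd_uv
    epochs = gain * aep_template(t, ap)[None, :] + _pink_noise(rng, n_epochs, len(t), sd)
    if ap.dc_sd_uv > 0 and sd > 0:
        epochs += rng.normal(0, ap.dc_sd_uv, size=(n_epochs, 1))
    return AEPEpochSet(
        epochs=epochs, t_ms=t, tone_db=tone_db, tone_hz=tone_hz,
        role=role, block=block, state=state, subject=subject,
    )


def make_oddball_sequence(
    rng: np.random.Generator, n_tones: int, deviant_frac: float = 0.2,
    min_standards_between: int = 2,
) -> np.ndarray:
    """Boolean deviant mask with >= min_standards_between standards between
    consecutive deviants (constructive gap allocation, always succeeds)."""
    n_dev = int(round(deviant_frac * n_tones))
    base = min_standards_between + 1
    slack = n_tones - n_dev * base
    if slack < 0:
        raise ValueError("too many deviants for the spacing constraint")
    extra = rng.multinomial(slack, np.ones(n_dev + 1) / (n_dev + 1))
    mask = np.zeros(n_tones, dtype=bool)
    pos = 0
    for i in range(n_dev):
        pos += extra[i]
        mask[pos] = True
        pos += base
    return mask
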