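"""Per-session oculomotor parameters from traces and detected events.

This is the feature layer: each task contributes named session-level
parameters (accuracy, reaction time, saccade kinematics, pursuit gains and
saccade rates, microsaccade statistics, fixation stability as BCEA, pupil
size and pupillary response, free-viewing statistics) that together form
the feature space the state decoder consumes.

Conventions:

* reaction time = go/target onset to onset of the first detected saccade
  with amplitude >= 2 deg (microsaccades never count as responses);
* saccade velocity features are net displacement / duration;
* pursuit gain is computed on desaccaded samples only, excluding the first
  200 ms after motion onset;
* BCEA = 2 k pi sigma_x sigma_y sqrt(1 - rho^2) with k = -ln(1 - P),
  default P = 0.68, over all fixation gaze samples;
* angle-from-horizontal features live in [0, 90] degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import (
    DetectionParams,
    SaccadeEvent,
    desaccade_mask,
    detect_saccades,
    compute_velocity,
    interpolate_blinks,
)
from .io import (
    EyeTrace,
    TrialMeta,
    SessionFeatures,
    FEATURE_KEYS,
    InsufficientDataError,
)


@dataclass
class TrialScore:
    """Outcome of one instructed saccade trial."""

    correct: bool
    no_response: bool
    broke_fixation: bool
    rt_ms: float  # NaN when no response saccade
    vel_deg_s: float
    dur_ms: float
    amp_deg: float


@dataclass
class PursuitFit:
    """Per-axis sinusoidal fit of desaccaded pursuit velocity."""

    axis: str
    gain: float
    phase_rad: float
    residual_rms: float
    n_samples: int


@dataclass
class FixationStats:
    bcea_deg2: float
    sigma_x: float
    sigma_y: float
    rho: float
    proportion: float
    pupil_size: float
    pupil_baseline: float
    pupil_response: float


@dataclass
class FreeViewStats:
    sacc_rate_hz: float
    amp_median_deg: float
    angle_deg: float
    gaze_histogram: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


MIN_RESPONSE_AMP_DEG = 2.0


def _response_saccade(events, after_ms, window_ms=800.0):
    for ev in events:
        if (
            ev.amplitude_deg >= MIN_RESPONSE_AMP_DEG
            and after_ms < ev.onset_ms <= after_ms + window_ms
        ):
            return ev
    return None


def score_saccade_trial(
    trace: EyeTrace,
    meta: TrialMeta,
    events: list[SaccadeEvent],
    response_window_ms: float = 800.0,
    fix_radius_deg: float = 2.0,
) -> TrialScore:
    """Score one anti-, pro- or delayed-saccade trial.

    The response saccade is the first >=2 deg saccade after the go signal;
    correctness is judged on the horizontal sign of its displacement versus
    the cue rule (pro: toward the target; anti: away from it).  Delayed
    trials additionally require that fixation was held through the delay:
    any >=2 deg saccade, or gaze leaving a 2 deg radius around the fixation
    point, before the go counts as a break (incorrect).  A trial without a
    response saccade is marked no-response and incorrect; its RT is NaN.
    """
    if meta.task not in ("anti_saccade", "pro_saccade", "delayed_saccade"):
        raise ValueError(f"not an instructed saccade task: {meta.task}")
    target_on = trace.event_time_ms("target_on")
    tx = trace.target_x_deg[trace.events["target_on"] + 2]
    target_sign = 1.0 if tx >= 0 else -1.0

    broke = False
    if meta.task == "delayed_saccade":
        go_ms = (
            trace.event_time_ms("go_signal") if "go_signal" in trace.events
            else trace.t_ms[-1]
        )
        for ev in events:
            if ev.amplitude_deg >= MIN_RESPONSE_AMP_DEG and target_on < ev.onset_ms < go_ms:
                broke = True
        x, _ = interpolate_blinks(trace.x_deg, trace.t_ms)
        y, _ = interpolate_blinks(trace.y_deg, trace.t_ms)
        delay = (trace.t_ms >= target_on) & (trace.t_ms < go_ms)
        if np.any(np.hypot(x[delay], y[delay]) > fix_radius_deg):
            broke = True
    else:
        # anti/pro: the target onset is the imperative go signal
        go_ms = (
            trace.event_time_ms("go_signal") if "go_signal" in trace.events
            else target_on
        )

    resp = _response_saccade(events, go_ms, response_window_ms)
    if resp is None or broke:
        return TrialScore(
            correct=False, no_response=resp is None, broke_fixation=broke,
            rt_ms=float("nan"), vel_deg_s=float("nan"),
            dur_ms=float("nan"), amp_deg=float("nan"),
        )
    dx_sign = 1.0 if np.cos(np.deg2rad(resp.direction_deg)) >= 0 else -1.0
    if meta.task == "anti_saccade":
        correct = dx_sign == -target_sign
    else:  # pro rule: toward the target
        correct = dx_sign == target_sign
    return TrialScore(
        correct=bool(correct), no_response=False, broke_fixation=False,
        rt_ms=float(resp.onset_ms - go_ms),
        vel_deg_s=resp.avg_vel_deg_s,
        dur_ms=resp.duration_ms,
        amp_deg=resp.amplitude_deg,
    )


# ---------------------------------------------------------------------------
# pursuit


def _target_velocity(trace, params=None):
    """Differentiate the commanded target channels (same stencil as gaze)."""
    tmp = EyeTrace(
        t_ms=trace.t_ms, x_deg=trace.target_x_deg, y_deg=trace.target_y_deg,
        pupil_au=trace.pupil_au, target_x_deg=trace.target_x_deg,
        target_y_deg=trace.target_y_deg, fs_hz=trace.fs_hz, events=trace.events,
    )
    return compute_velocity(tmp, params)


def pursuit_linear_metrics(
    trace: EyeTrace,
    events: list[SaccadeEvent],
    pad_ms: float = 10.0,
    settle_ms: float = 200.0,
    params: DetectionParams | None = None,
) -> tuple[float, float]:
    """(pursuit gain, saccade rate in Hz) for constant-speed linear pursuit.

    Gain is the mean desaccaded eye velocity along the motion axis divided
    by the target speed, over samples later than ``settle_ms`` after motion
    onset; samples near target-direction reversals (where speed is
    undefined) are excluded.  The saccade rate uses all detected events in
    the same analysis window.
    """
    vx, vy, _ = compute_velocity(trace, params)
    tvx, tvy, tspeed = _target_velocity(trace, params)
    t0 = trace.event_time_ms("target_on") if "target_on" in trace.events else 0.0
    in_window = trace.t_ms >= t0 + settle_ms
    axis_is_x = np.nanvar(tvx) >= np.nanvar(tvy)
    tv = tvx if axis_is_x else tvy
    ev_axis = vx if axis_is_x else vy
    v_nom = np.nanmax(np.abs(tv))
    if not np.isfinite(v_nom) or v_nom <= 0:
        raise ValueError("target channel carries no motion")
    keep = (
        desaccade_mask(trace, events, pad_ms)
        & in_window
        & np.isfinite(ev_axis)
        & np.isfinite(tv)
        & (np.abs(tv) > 0.5 * v_nom)  # excludes reversal neighbourhoods
    )
    duration_s = np.sum(in_window) / trace.fs_hz
    n_ev = sum(1 for e in events if e.onset_ms >= t0 + settle_ms)
    rate = n_ev / duration_s if duration_s > 0 else float("nan")
    if keep.sum() < 0.5 * in_window.sum():
        warnings.warn(
            "fewer than 50% of pursuit samples usable after desaccading",
            stacklevel=2,
        )
    if keep.sum() == 0:
        return float("nan"), rate
    gain = float(
        np.mean(ev_axis[keep] * np.sign(tv[keep])) / np.mean(np.abs(tv[keep]))
    )
    return gain, rate


def _infer_sinusoid_omega(t_s, pos):
    """Angular frequency of a clean sinusoid from its zero crossings."""
    sign = np.sign(pos - np.mean(pos))
    cross = np.flatnonzero(np.diff(sign) != 0)
    if len(cross) < 2:
        raise ValueError("cannot infer target frequency (too few crossings)")
    half_period = np.mean(np.diff(t_s[cross]))
    return np.pi / half_period


def _fit_axis(t_s, eye_v, target_v, omega, axis):
    basis = np.column_stack([np.cos(omega * t_s), np.sin(omega * t_s)])
    ce, *_ = np.linalg.lstsq(basis, eye_v, rcond=None)
    ct, *_ = np.linalg.lstsq(basis, target_v, rcond=None)
    amp_t = float(np.hypot(*ct))
    gain = float(np.hypot(*ce) / amp_t) if amp_t > 0 else float("nan")
    phase = float(np.arctan2(-ce[1], ce[0]) - np.arctan2(-ct[1], ct[0]))
    phase = (phase + np.pi) % (2 * np.pi) - np.pi
    resid = eye_v - basis @ ce
    return PursuitFit(
        axis=axis, gain=gain, phase_rad=-phase,  # positive = eye lags target
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_samples=len(eye_v),
    )


def pursuit_lissajous_metrics(
    trace: EyeTrace,
    events: list[SaccadeEvent],
    target_params: dict | None = None,
    pad_ms: float = 10.0,
    settle_ms: float = 200.0,
    params: DetectionParams | None = None,
) -> tuple[PursuitFit, PursuitFit, float]:
    """Per-axis pursuit gain for 2D Lissajous tracking.

    Desaccaded eye velocity on each cardinal axis is least-squares fit to a
    sinusoid at the target frequency; gain is the fitted amplitude ratio of
    eye to target velocity.  Target frequencies come from ``target_params``
    (keys fx_hz/fy_hz) or are inferred from the commanded target channel's
    zero crossings.
    """
    vx, vy, _ = compute_velocity(trace, params)
    tvx, tvy, _ = _target_velocity(trace, params)
    t0 = trace.event_time_ms("target_on") if "target_on" in trace.events else 0.0
    t_s = (trace.t_ms - t0) / 1000.0
    in_window = trace.t_ms >= t0 + settle_ms
    keep = desaccade_mask(trace, events, pad_ms) & in_window
    fits = []
    for axis, ev, tv, key in (("x", vx, tvx, "fx_hz"), ("y", vy, tvy, "fy_hz")):
        if target_params is not None and key in target_params:
            omega = 2.0 * np.pi * target_params[key]
        else:
            pos = trace.target_x_deg if axis == "x" else trace.target_y_deg
            omega = _infer_sinusoid_omega(t_s[in_window], pos[in_window])
        ok = keep & np.isfinite(ev) & np.isfinite(tv)
        if ok.sum() < 20:
            raise InsufficientDataError("too few desaccaded pursuit samples")
        fits.append(_fit_axis(t_s[ok], ev[ok], tv[ok], omega, axis))
    duration_s = np.sum(in_window) / trace.fs_hz
    n_ev = sum(1 for e in events if e.onset_ms >= t0 + settle_ms)
    rate = n_ev / duration_s if duration_s > 0 else float("nan")
    return fits[0], fits[1], rate


# ---------------------------------------------------------------------------
# fixation


def bcea(x: np.ndarray, y: np.ndarray, proportion: float = 0.68) -> float:
    """Bivariate contour ellipse area, 2 k pi sx sy sqrt(1-rho^2)."""
    if not 0.0 < proportion < 1.0:
        raise ValueError("proportion must be in (0,1)")
    k = -np.log(1.0 - proportion)
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        return 0.0
    rho = float(np.corrcoef(x, y)[0, 1])
    return float(2.0 * k * np.pi * sx * sy * np.sqrt(max(1.0 - rho**2, 0.0)))


def fixation_metrics(
    trace: EyeTrace,
    events: list[SaccadeEvent],
    proportion: float = 0.68,
) -> tuple[FixationStats, dict]:
    """Fixation stability, pupil metrics and microsaccade aggregates.

    BCEA uses all gaze samples of the trial (overall eye position, not
    desaccaded).  Pupil windows: size = mean of first 500 ms, baseline =
    mean of first 200 ms, response = mean of last 1000 ms minus baseline.
    Microsaccade aggregates cover events with amplitude below the
    microsaccade bound.
    """
    if trace.n_samples < 100:
        raise InsufficientDataError("fewer than 100 fixation samples")
    x, _ = interpolate_blinks(trace.x_deg, trace.t_ms)
    y, _ = interpolate_blinks(trace.y_deg, trace.t_ms)
    pupil, _ = interpolate_blinks(trace.pupil_au, trace.t_ms)
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    rho = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else 0.0
    area = bcea(x, y, proportion)

    t = trace.t_ms - trace.t_ms[0]
    size = float(np.mean(pupil[t < 500.0]))
    baseline = float(np.mean(pupil[t < 200.0]))
    response = float(np.mean(pupil[t >= t[-1] - 1000.0]) - baseline)

    micro = [e for e in events if e.is_microsaccade]
    agg = {
        "ms_angle_deg": float(np.mean([e.angle_from_horizontal_deg for e in micro]))
        if micro else float("nan"),
        "ms_vel": float(np.mean([e.avg_vel_deg_s for e in micro]))
        if micro else float("nan"),
        "ms_dur": float(np.mean([e.duration_ms for e in micro]))
        if micro else float("nan"),
        "ms_amp": float(np.mean([e.amplitude_deg for e in micro]))
        if micro else float("nan"),
        "ms_down_frac": float(np.mean([e.is_downward for e in micro]))
        if micro else float("nan"),
        "n_microsaccades": len(micro),
    }
    return (
        FixationStats(
            bcea_deg2=area, sigma_x=sx, sigma_y=sy, rho=rho,
            proportion=proportion, pupil_size=size,
            pupil_baseline=baseline, pupil_response=response,
        ),
        agg,
    )


def freeview_metrics(
    trace: EyeTrace,
    events: list[SaccadeEvent],
    grid_deg: float = 1.0,
    extent_deg: float = 12.0,
) -> FreeViewStats:
    """Free-viewing saccade statistics plus a QC gaze histogram."""
    duration_s = trace.duration_s
    rate = len(events) / duration_s if duration_s > 0 else float("nan")
    if events:
        amp_med = float(np.median([e.amplitude_deg for e in events]))
        angle = float(np.mean([e.angle_from_horizontal_deg for e in events]))
    else:
        amp_med = float("nan")
        angle = float("nan")
    edges = np.arange(-extent_deg, extent_deg + grid_deg / 2, grid_deg)
    x, _ = interpolate_blinks(trace.x_deg, trace.t_ms)
    y, _ = interpolate_blinks(trace.y_deg, trace.t_ms)
    hist, xe, ye = np.histogram2d(x, y, bins=(edges, edges))
    return FreeViewStats(
        sacc_rate_hz=rate, amp_median_deg=amp_med, angle_deg=angle,
        gaze_histogram=hist, x_edges=xe, y_edges=ye,
    )


# ---------------------------------------------------------------------------
# session aggregation


def _has_long_gap(trace: EyeTrace, max_gap_ms: float = 50.0) -> bool:
    try:
        _, flag = interpolate_blinks(trace.x_deg, trace.t_ms, max_gap_ms)
    except ValueError:
        return True
    return flag


def aggregate_session(task_rows: dict) -> dict:
    """Combine per-trial metric dicts (keyed by task) into session means."""
    out: dict = {}
    for rows in task_rows.values():
        if not rows:
            continue
        keys = rows[0].keys()
        for k in keys:
            vals = [r[k] for r in rows if np.isfinite(r.get(k, np.nan))]
            out[k] = float(np.mean(vals)) if vals else float("nan")
    return out


def extract_session_features(
    trials: list[tuple[EyeTrace, TrialMeta]],
    det_params: DetectionParams | None = None,
    bcea_proportion: float = 0.68,
) -> SessionFeatures:
    """Run detection and all task metrics over one session's trials.

    Trials with blink gaps too long to interpolate are excluded from
    aggregation.  Tasks with no usable trial leave their features NaN.
    Fixed-threshold detection is used for instructed/pursuit tasks,
    adaptive for fixation and free viewing.
    """
    if not trials:
        raise InsufficientDataError("no trials")
    det_params = det_params or DetectionParams()
    meta0 = trials[0][1]
    rows: dict = {t: [] for t in (
        "anti_saccade", "pro_saccade", "delayed_saccade", "linear_pursuit",
        "lissajous_pursuit", "fixation", "free_viewing",
    )}
    fv_median_amps: list = []
    for trace, meta in trials:
        if _has_long_gap(trace, det_params.blink_interp_max_ms):
            continue
        task = meta.task
        if task in ("anti_saccade", "pro_saccade", "delayed_saccade"):
            events = detect_saccades(trace, det_params, mode="fixed")
            s = score_saccade_trial(trace, meta, events)
            prefix = {"anti_saccade": "anti", "pro_saccade": "pro",
                      "delayed_saccade": "delay"}[task]
            rows[task].append({
                f"{prefix}_accuracy": float(s.correct),
                f"{prefix}_rt_ms": s.rt_ms,
                f"{prefix}_sacc_vel": s.vel_deg_s,
                f"{prefix}_sacc_dur": s.dur_ms,
                f"{prefix}_sacc_amp": s.amp_deg,
            })
        elif task == "linear_pursuit":
            events = detect_saccades(trace, det_params, mode="fixed")
            gain, s_rate = pursuit_linear_metrics(trace, events, params=det_params)
            rows[task].append({"lin_gain": gain, "lin_sacc_rate": s_rate})
        elif task == "lissajous_pursuit":
            events = detect_saccades(trace, det_params, mode="fixed")
            fx, fy, s_rate = pursuit_lissajous_metrics(
                trace, events, params=det_params
            )
            rows[task].append({
                "lis_gain_x": fx.gain, "lis_gain_y": fy.gain,
                "lis_sacc_rate": s_rate,
            })
        elif task == "fixation":
            events = detect_saccades(trace, det_params, mode="adaptive")
            fx_stats, agg = fixation_metrics(trace, events, bcea_proportion)
            rows[task].append({
                "bcea_deg2": fx_stats.bcea_deg2,
                "pupil_size": fx_stats.pupil_size,
                "pupil_response": fx_stats.pupil_response,
                "ms_angle_deg": agg["ms_angle_deg"],
                "ms_vel": agg["ms_vel"],
                "ms_dur": agg["ms_dur"],
                "ms_amp": agg["ms_amp"],
                "ms_down_frac": agg["ms_down_frac"],
            })
        elif task == "free_viewing":
            events = detect_saccades(trace, det_params, mode="adaptive")
            fv = freeview_metrics(trace, events)
            rows[task].append({
                "fv_sacc_rate": fv.sacc_rate_hz,
                "fv_angle_deg": fv.angle_deg,
            })
            fv_median_amps.extend([e.amplitude_deg for e in events])

    feats = {k: float("nan") for k in FEATURE_KEYS}
    feats.update(aggregate_session(rows))
    feats["fv_sacc_amp_med"] = (
        float(np.median(fv_median_amps)) if fv_median_amps else float("nan")
    )
    return SessionFeatures(
        subject=meta0.subject, state=meta0.state,
        session_id=meta0.session_id, features=feats,
    )


def speed_accuracy_correlation(
    features: list[SessionFeatures], min_sessions: int = 3
) -> dict:
    """Pearson r between anti-saccade accuracy and RT, per state.

    Sessions with missing values are skipped; states with fewer than
    ``min_sessions`` usable sessions, or zero variance in either variable,
    map to NaN.
    """
    out = {}
    for state in sorted({f.state for f in features}):
        acc = []
        rt = []
        for f in features:
            if f.state != state:
                continue
            a = f.features.get("anti_accuracy", np.nan)
            r = f.features.get("anti_rt_ms", np.nan)
            if np.isfinite(a) and np.isfinite(r):
                acc.append(a)
                rt.append(r)
        if len(acc) < min_sessions or np.std(acc) == 0 or np.std(rt) == 0:
            out[state] = float("nan")
            continue
        out[state] = float(stats.pearsonr(acc, rt)[0])
    return out
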