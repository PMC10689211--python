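"""Saccade and microsaccade detection from gaze traces.

Velocity is estimated with the standard five-point smoothing differentiator
used throughout the microsaccade literature,

    v[i] = (x[i+1] + x[i+2] - x[i-1] - x[i-2]) * fs / 6,

optionally preceded by a short boxcar position smoother.  Two thresholding
modes are supported: a fixed speed threshold (default 30 deg/s) for task
saccades, and an adaptive median-based threshold (lambda multiples of a
robust per-axis SD, combined elliptically) for microsaccades during fixation
and free viewing.  Candidate runs shorter than a minimum duration are
dropped, runs separated by less than a merge interval are merged, and event
boundaries are then extended outward to the adjacent local speed minima so
that kinematics cover the full displacement.

Microsaccades are saccades with amplitude below ``micro_amp_max``
(conventionally 2 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EyeTrace


@dataclass
class DetectionParams:
    """Detection thresholds; all config-exposed.

    smooth_window
        boxcar width (samples) applied to position before differentiation.
    fixed_threshold_deg_s
        speed threshold for ``mode="fixed"``.
    lambda_sd
        multiplier on the robust per-axis velocity SD for ``mode="adaptive"``.
    adaptive_floor_deg_s
        lower bound on each axis threshold, so noiseless traces do not
        produce a degenerate zero threshold.
    min_duration_ms / merge_interval_ms
        run acceptance / merging rules.
    micro_amp_max_deg
        amplitude bound below which an event counts as a microsaccade.
    blink_interp_max_ms
        blink gaps up to this length are linearly interpolated before
        differentiation; longer gaps flag the trial.
    """

    smooth_window: int = 3
    fixed_threshold_deg_s: float = 30.0
    lambda_sd: float = 6.0
    adaptive_floor_deg_s: float = 5.0
    min_duration_ms: float = 8.0
    merge_interval_ms: float = 20.0
    micro_amp_max_deg: float = 2.0
    blink_interp_max_ms: float = 50.0
    boundary_min_speed_deg_s: float = 1.7

    def __post_init__(self):
        for name in (
            "smooth_window", "fixed_threshold_deg_s", "lambda_sd",
            "adaptive_floor_deg_s", "min_duration_ms", "merge_interval_ms",
            "micro_amp_max_deg", "blink_interp_max_ms", "boundary_min_speed_deg_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"DetectionParams.{name} must be positive")


@dataclass
class SaccadeEvent:
    """One detected (micro)saccade and its kinematics.

    ``direction_deg`` is atan2 of the net displacement (0 = rightward,
    counter-clockwise positive, in [0, 360)); ``angle_from_horizontal_deg``
    folds direction into [0, 90] as distance from the horizontal meridian.
    ``avg_vel_deg_s`` is net displacement / duration; ``mean_vel_deg_s`` is
    the mean sample speed within the event extent.
    """

    onset_ms: float
    offset_ms: float
    duration_ms: float
    amplitude_deg: float
    peak_vel_deg_s: float
    mean_vel_deg_s: float
    avg_vel_deg_s: float
    direction_deg: float
    angle_from_horizontal_deg: float
    is_downward: bool
    is_microsaccade: bool
    onset_idx: int
    offset_idx: int


def interpolate_blinks(
    x: np.ndarray, t_ms: np.ndarray, max_gap_ms: float = 50.0
) -> tuple[np.ndarray, bool]:
    """Linearly interpolate NaN gaps up to ``max_gap_ms``.

    Returns the filled signal and a flag that is True when any longer gap
    remained (such trials should be treated with caution downstream; the
    long gap itself is still interpolated so detection does not crash).
    """
    x = np.asarray(x, dtype=float).copy()
    bad = ~np.isfinite(x)
    if not bad.any():
        return x, False
    long_gap = False
    # locate contiguous NaN runs
    edges = np.flatnonzero(np.diff(bad.astype(int)))
    starts = list(edges[bad[edges + 1]] + 1) if len(edges) else []
    if bad[0]:
        starts = [0] + starts
    dt = t_ms[1] - t_ms[0]
    for s in starts:
        e = s
        while e + 1 < len(x) and bad[e + 1]:
            e += 1
        if (e - s + 1) * dt > max_gap_ms:
            long_gap = True
    good = np.flatnonzero(~bad)
    if len(good) < 2:
        raise ValueError("trace is (almost) entirely missing")
    x[bad] = np.interp(t_ms[bad], t_ms[good], x[good])
    return x, long_gap


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="valid")
    return out[: len(x)]


def compute_velocity(
    trace: EyeTrace, params: DetectionParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample 2D velocity (deg/s) and speed.

    Blink gaps up to the configured maximum are interpolated first.  The
    first and last two samples are invalid (NaN).  Exact for linear signals.
    """
    params = params or DetectionParams()
    if trace.n_samples < 5:
        raise ValueError("trace shorter than 5 samples")
    fs = trace.fs_hz
    vx = np.full(trace.n_samples, np.nan)
    vy = np.full(trace.n_samples, np.nan)
    for arr, out in ((trace.x_deg, vx), (trace.y_deg, vy)):
        filled, _ = interpolate_blinks(arr, trace.t_ms, params.blink_interp_max_ms)
        s = _smooth(filled, params.smooth_window)
        out[2:-2] = (s[3:-1] + s[4:] - s[1:-3] - s[:-4]) * fs / 6.0
    # edge samples touched by the stencil and the boxcar are invalid
    margin = 2 + params.smooth_window // 2
    vx[:margin] = vx[len(vx) - margin:] = np.nan
    vy[:margin] = vy[len(vy) - margin:] = np.nan
    speed = np.hypot(vx, vy)
    return vx, vy, speed


def _runs_above(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, end) index pairs."""
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def detect_saccades(
    trace: EyeTrace,
    params: DetectionParams | None = None,
    mode: str = "fixed",
) -> list[SaccadeEvent]:
    """Detect saccadic events in one trace.

    mode="fixed" uses the fixed speed threshold (task saccades);
    mode="adaptive" uses the elliptic median-based threshold (fixation /
    free-viewing traces).  Returns an empty list when nothing crosses
    threshold.
    """
    params = params or DetectionParams()
    if mode not in ("fixed", "adaptive"):
        raise ValueError(f"unknown detection mode {mode!r}")
    vx, vy, speed = compute_velocity(trace, params)
    valid = np.isfinite(speed)
    if mode == "fixed":
        above = valid & (speed > params.fixed_threshold_deg_s)
    else:
        thr = []
        for v in (vx, vy):
            vv = v[valid]
            sd = np.sqrt(
                max(np.median(vv**2) - np.median(vv) ** 2, 0.0)
            )
            thr.append(max(params.lambda_sd * sd, params.adaptive_floor_deg_s))
        ellip = np.zeros_like(speed)
        ellip[valid] = (vx[valid] / thr[0]) ** 2 + (vy[valid] / thr[1]) ** 2
        above = valid & (ellip > 1.0)

    runs = _runs_above(above)
    if not runs:
        return []

    dt_ms = 1000.0 / trace.fs_hz
    merge_n = params.merge_interval_ms / dt_ms
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 < merge_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    merged = [
        (s, e) for s, e in merged if (e - s + 1) * dt_ms >= params.min_duration_ms
    ]

    # extend boundaries outward through the slow tails of each saccade:
    # walk while speed keeps decreasing and stays above a small absolute
    # cutoff (the cutoff keeps the boundary near the true movement edge
    # instead of drifting into the flat baseline of noiseless traces)
    spd = np.where(valid, speed, 0.0)
    prev_end = -1
    events: list[SaccadeEvent] = []
    x, _ = interpolate_blinks(trace.x_deg, trace.t_ms, params.blink_interp_max_ms)
    y, _ = interpolate_blinks(trace.y_deg, trace.t_ms, params.blink_interp_max_ms)
    for s, e in merged:
        cut = params.boundary_min_speed_deg_s
        while (
            s - 1 > prev_end and s - 1 >= 2
            and spd[s - 1] < spd[s] and spd[s - 1] >= cut
        ):
            s -= 1
        while (
            e + 1 < trace.n_samples - 2
            and spd[e + 1] < spd[e] and spd[e + 1] >= cut
        ):
            e += 1
        prev_end = e
        dx = x[e] - x[s]
        dy = y[e] - y[s]
        amp = float(np.hypot(dx, dy))
        # sub-sample boundary refinement: extrapolate the speed ramp at each
        # edge to its zero crossing (clamped to one sample) to remove most of
        # the 1-sample quantisation of onset/offset and duration
        t_on = float(trace.t_ms[s])
        t_off = float(trace.t_ms[e])
        if s - 1 >= 0 and spd[s - 1] < cut <= spd[s]:
            t_on -= dt_ms * min(spd[s] / (spd[s] - spd[s - 1]), 1.0)
        if e + 1 < trace.n_samples and spd[e + 1] < cut <= spd[e]:
            t_off += dt_ms * min(spd[e] / (spd[e] - spd[e + 1]), 1.0)
        dur = t_off - t_on
        direction = float(np.degrees(np.arctan2(dy, dx)) % 360.0)
        folded = direction % 180.0
        angle = float(min(folded, 180.0 - folded))
        seg = spd[s : e + 1]
        events.append(
            SaccadeEvent(
                onset_ms=t_on,
                offset_ms=t_off,
                duration_ms=float(dur),
                amplitude_deg=amp,
                peak_vel_deg_s=float(np.max(seg)),
                mean_vel_deg_s=float(np.mean(seg)),
                avg_vel_deg_s=float(amp / (dur / 1000.0)) if dur > 0 else 0.0,
                direction_deg=direction,
                angle_from_horizontal_deg=angle,
                is_downward=bool(dy < 0),
                is_microsaccade=bool(amp < params.micro_amp_max_deg),
                onset_idx=int(s),
                offset_idx=int(e),
            )
        )
    return events


def desaccade_mask(
    trace: EyeTrace, events: list[SaccadeEvent], pad_ms: float = 10.0
) -> np.ndarray:
    """Boolean per-sample mask, True = included (outside every event +/- pad)."""
    mask = np.ones(trace.n_samples, dtype=bool)
    pad_n = int(round(pad_ms * trace.fs_hz / 1000.0))
    for ev in events:
        lo = max(ev.onset_idx - pad_n, 0)
        hi = min(ev.offset_idx + pad_n, trace.n_samples - 1)
        mask[lo : hi + 1] = False
    return mask
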