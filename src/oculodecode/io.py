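"""Data model and tabular I/O.

Everything downstream consumes three kinds of objects: :class:`EyeTrace`
(uniformly sampled gaze/pupil/target signals for one trial, with
sample-indexed event markers), :class:`SessionFeatures` (one session's named
vector of oculomotor parameters) and :class:`AEPEpochSet` (stimulus-locked
EEG epochs from the auditory oddball paradigm).

File formats are deliberately plain, human-inspectable TSV:

* trace files are long format, one row per sample, columns
  ``session_id subject state task trial_id t_ms eye_x_deg eye_y_deg
  pupil_au target_x_deg target_y_deg event_code``;
* feature tables are one row per session, metadata columns followed by the
  canonical feature columns of :data:`FEATURE_KEYS`;
* AEP epoch files are long format with one row per (epoch, time point).

Coordinates are screen-centred degrees of visual angle, +x rightward,
+y upward, so "downward" always means negative y.  Blinks are encoded as
empty fields (missing gaze/pupil).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

STATES = ("saline", "pcp", "ketamine")

TASKS = (
    "anti_saccade",
    "pro_saccade",
    "delayed_saccade",
    "linear_pursuit",
    "lissajous_pursuit",
    "fixation",
    "free_viewing",
)

#: sample-indexed event marker codes used in the trace event_code column
EVENT_CODES = {
    "fixation_on": 1,
    "cue_on": 2,
    "target_on": 3,
    "go_signal": 4,
    "trial_end": 9,
}
CODE_NAMES = {v: k for k, v in EVENT_CODES.items()}

#: canonical session-feature names, in canonical column order
FEATURE_KEYS = (
    "anti_accuracy", "anti_rt_ms", "anti_sacc_vel", "anti_sacc_dur", "anti_sacc_amp",
    "pro_accuracy", "pro_rt_ms", "pro_sacc_vel", "pro_sacc_dur", "pro_sacc_amp",
    "delay_accuracy", "delay_rt_ms", "delay_sacc_vel", "delay_sacc_dur", "delay_sacc_amp",
    "lin_gain", "lin_sacc_rate",
    "lis_sacc_rate", "lis_gain_x", "lis_gain_y",
    "ms_angle_deg", "ms_vel", "ms_dur", "ms_amp", "ms_down_frac",
    "bcea_deg2", "pupil_size", "pupil_response",
    "fv_sacc_rate", "fv_sacc_amp_med", "fv_angle_deg",
)

TRACE_COLUMNS = [
    "session_id", "subject", "state", "task", "trial_id", "t_ms",
    "eye_x_deg", "eye_y_deg", "pupil_au", "target_x_deg", "target_y_deg",
    "event_code",
]

AEP_COLUMNS = [
    "epoch_id", "tone_db", "tone_hz", "role", "block", "state", "subject",
    "t_ms", "amp_uv",
]


class FormatError(ValueError):
    """A file does not conform to the documented tabular layout."""


class SamplingError(ValueError):
    """Sample times are not uniformly spaced within tolerance."""


class SchemaError(ValueError):
    """Feature records do not share the canonical key set."""


class InsufficientDataError(ValueError):
    """Too little data to compute the requested quantity."""


@dataclass
class EyeTrace:
    """Uniformly sampled gaze/pupil/target signals for one trial.

    ``events`` maps marker names (see :data:`EVENT_CODES`) to sample indices.
    Missing gaze/pupil samples (blinks) are NaN.
    """

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    pupil_au: np.ndarray
    target_x_deg: np.ndarray
    target_y_deg: np.ndarray
    fs_hz: float
    events: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def event_time_ms(self, name: str) -> float:
        return float(self.t_ms[self.events[name]])

    def validate(self, rtol: float = 0.01) -> None:
        """Check the uniform-sampling and marker invariants."""
        if self.n_samples < 2:
            raise SamplingError("trace has fewer than 2 samples")
        dt = np.diff(self.t_ms)
        nominal = 1000.0 / self.fs_hz
        if np.any(dt <= 0):
            raise SamplingError("t_ms is not strictly increasing")
        if np.any(np.abs(dt - nominal) > rtol * nominal):
            raise SamplingError(
                f"non-uniform sampling: max deviation "
                f"{np.max(np.abs(dt - nominal)):.3f} ms from nominal {nominal:.3f} ms"
            )
        for name, idx in self.events.items():
            if not 0 <= idx < self.n_samples:
                raise FormatError(f"event {name!r} index {idx} outside trace")


@dataclass
class TrialMeta:
    """Per-trial metadata; ``ground_truth`` is generator-only."""

    session_id: str
    subject: str
    state: str
    task: str
    trial_id: int
    cue: str = "none"  # anti | pro | none
    target_direction_deg: float = float("nan")
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.cue in ("anti", "pro") and self.task not in (
            "anti_saccade", "pro_saccade", "delayed_saccade"
        ):
            raise ValueError("anti/pro cue only valid for saccade tasks")


@dataclass
class SessionFeatures:
    """One session's named oculomotor parameter vector plus labels."""

    subject: str
    state: str
    session_id: str
    features: dict = field(default_factory=dict)

    def is_complete(self) -> bool:
        return all(
            k in self.features and np.isfinite(self.features[k]) for k in FEATURE_KEYS
        )


@dataclass
class AEPEpochSet:
    """Stimulus-locked EEG epochs for one tone condition.

    ``epochs`` is an (n_epochs, n_time) matrix in microvolts; ``t_ms`` is
    relative to tone onset and includes the pre-stimulus baseline span.
    """

    epochs: np.ndarray
    t_ms: np.ndarray
    tone_db: int
    tone_hz: int
    role: str  # standard | deviant
    block: str = "A"
    state: str = "saline"
    subject: str = "N"

    def __post_init__(self):
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        if self.epochs.shape[1] != len(self.t_ms):
            raise FormatError("epoch matrix and time axis length mismatch")
        if self.role not in ("standard", "deviant"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


# ---------------------------------------------------------------------------
# trace files


def write_trace_file(trials: Iterable[tuple[EyeTrace, TrialMeta]], path) -> None:
    """Write trials to a long-format trace TSV (one row per sample)."""
    frames = []
    for trace, meta in trials:
        code = np.zeros(trace.n_samples, dtype=int)
        for name, idx in trace.events.items():
            code[idx] = EVENT_CODES[name]
        frames.append(
            pd.DataFrame(
                {
                    "session_id": meta.session_id,
                    "subject": meta.subject,
                    "state": meta.state,
                    "task": meta.task,
                    "trial_id": meta.trial_id,
                    "t_ms": trace.t_ms,
                    "eye_x_deg": trace.x_deg,
                    "eye_y_deg": trace.y_deg,
                    "pupil_au": trace.pupil_au,
                    "target_x_deg": trace.target_x_deg,
                    "target_y_deg": trace.target_y_deg,
                    "event_code": code,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.5f", na_rep="")


def read_trace_file(path) -> list[tuple[EyeTrace, TrialMeta]]:
    """Read a long-format trace TSV back into per-trial objects.

    Trials are split on (session_id, trial_id) groups; each must contain
    exactly one ``trial_end`` marker.  The sampling rate is inferred from the
    median sample interval and validated (1% uniformity tolerance).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trace file missing mandatory column(s): {missing}")
    out = []
    for (sid, tid), g in df.groupby(["session_id", "trial_id"], sort=False):
        t = g["t_ms"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(t) < 2:
            raise SamplingError(f"trial {sid}/{tid}: fewer than 2 samples")
        nominal = float(np.median(dt))
        fs = 1000.0 / nominal
        codes = g["event_code"].to_numpy(dtype=int)
        events = {CODE_NAMES[c]: i for i, c in enumerate(codes) if c != 0}
        if int(np.sum(codes == EVENT_CODES["trial_end"])) != 1:
            raise FormatError(f"trial {sid}/{tid}: needs exactly one trial_end marker")
        trace = EyeTrace(
            t_ms=t,
            x_deg=g["eye_x_deg"].to_numpy(dtype=float),
            y_deg=g["eye_y_deg"].to_numpy(dtype=float),
            pupil_au=g["pupil_au"].to_numpy(dtype=float),
            target_x_deg=g["target_x_deg"].to_numpy(dtype=float),
            target_y_deg=g["target_y_deg"].to_numpy(dtype=float),
            fs_hz=fs,
            events=events,
        )
        trace.validate()
        task = str(g["task"].iloc[0])
        # the cue is implied by the task in this battery
        cue = {"anti_saccade": "anti", "pro_saccade": "pro",
               "delayed_saccade": "pro"}.get(task, "none")
        meta = TrialMeta(
            session_id=str(sid),
            subject=str(g["subject"].iloc[0]),
            state=str(g["state"].iloc[0]),
            task=task,
            trial_id=int(tid),
            cue=cue,
        )
        out.append((trace, meta))
    return out


# ---------------------------------------------------------------------------
# feature tables

_FEATURE_META = ["session_id", "subject", "state"]


def write_features(features: list[SessionFeatures], path) -> None:
    """Write one row per session: metadata columns then canonical features."""
    canon = set(FEATURE_KEYS)
    for sf in features:
        if set(sf.features) != canon:
            extra = sorted(set(sf.features) - canon)
            lack = sorted(canon - set(sf.features))
            raise SchemaError(
                f"session {sf.session_id}: non-canonical feature keys "
                f"(extra={extra}, missing={lack})"
            )
    rows = [
        {
            "session_id": sf.session_id,
            "subject": sf.subject,
            "state": sf.state,
            **{k: sf.features[k] for k in FEATURE_KEYS},
        }
        for sf in features
    ]
    df = pd.DataFrame(rows, columns=_FEATURE_META + list(FEATURE_KEYS))
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.8g")


def read_features(path) -> list[SessionFeatures]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _FEATURE_META + list(FEATURE_KEYS) if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing column(s): {missing}")
    return [
        SessionFeatures(
            subject=str(r["subject"]),
            state=str(r["state"]),
            session_id=str(r["session_id"]),
            features={k: float(r[k]) for k in FEATURE_KEYS},
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# AEP epoch files


def write_aep_file(epoch_sets: Iterable[AEPEpochSet], path) -> None:
    """Write epoch sets to a long-format TSV (one row per epoch sample)."""
    frames = []
    offset = 0
    for es in epoch_sets:
        n, nt = es.epochs.shape
        frames.append(
            pd.DataFrame(
                {
                    "epoch_id": np.repeat(np.arange(offset, offset + n), nt),
                    "tone_db": es.tone_db,
                    "tone_hz": es.tone_hz,
                    "role": es.role,
                    "block": es.block,
                    "state": es.state,
                    "subject": es.subject,
                    "t_ms": np.tile(es.t_ms, n),
                    "amp_uv": es.epochs.ravel(),
                }
            )
        )
        offset += n
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=AEP_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_aep_file(path) -> list[AEPEpochSet]:
    """Read epoch sets back, one per (tone, role, block, state, subject)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in AEP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"AEP file missing column(s): {missing}")
    out = []
    keys = ["tone_db", "tone_hz", "role", "block", "state", "subject"]
    for vals, g in df.groupby(keys, sort=False):
        cond = dict(zip(keys, vals))
        t_axis = np.sort(g["t_ms"].unique())
        mat = (
            g.pivot_table(index="epoch_id", columns="t_ms", values="amp_uv", sort=True)
            .to_numpy()
        )
        out.append(
            AEPEpochSet(
                epochs=mat,
                t_ms=t_axis,
                tone_db=int(cond["tone_db"]),
                tone_hz=int(cond["tone_hz"]),
                role=str(cond["role"]),
                block=str(cond["block"]),
                state=str(cond["state"]),
                subject=str(cond["subject"]),
            )
        )
    return out
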