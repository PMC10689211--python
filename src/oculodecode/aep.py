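"""Auditory-evoked-potential analysis for the oddball paradigm.

Epochs locked to tone onset are baseline-corrected (pre-stimulus window
mean subtracted per epoch) and averaged into an AEP waveform.  Condition
contrasts use the peak-to-trough modulation within a post-stimulus window,
a pointwise two-sided Wilcoxon rank-sum mask (per-point p < alpha, no
multiplicity correction — mirroring exploratory per-point significance
ticks), and the mismatch-negativity index: the deviant-minus-standard
difference waveform for the same physical tone, summarised as the mean
difference in a 100-200 ms window around the N2 component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import AEPEpochSet

DEFAULT_BASELINE_MS = (-100.0, 0.0)
DEFAULT_P2T_WINDOW_MS = (0.0, 300.0)
DEFAULT_MMN_WINDOW_MS = (100.0, 200.0)


@dataclass
class AEPWaveform:
    """Trial-averaged, baseline-corrected evoked potential."""

    t_ms: np.ndarray
    amp_uv: np.ndarray
    n_trials: int
    labels: dict = field(default_factory=dict)


def _baseline_correct(epochs: np.ndarray, t_ms: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    sel = (t_ms >= lo) & (t_ms < hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    if t_ms[sel].max() > 0:
        raise ValueError("baseline window must lie in the pre-stimulus span")
    return epochs - epochs[:, sel].mean(axis=1, keepdims=True)


def average_aep(
    epochs: AEPEpochSet, baseline_window=DEFAULT_BASELINE_MS
) -> AEPWaveform:
    """Baseline-correct each epoch, then average across epochs."""
    if epochs.n_epochs < 1 or epochs.epochs.size == 0:
        raise ValueError("empty epoch set")
    corrected = _baseline_correct(epochs.epochs, epochs.t_ms, baseline_window)
    return AEPWaveform(
        t_ms=epochs.t_ms.copy(),
        amp_uv=corrected.mean(axis=0),
        n_trials=epochs.n_epochs,
        labels={
            "tone_db": epochs.tone_db, "tone_hz": epochs.tone_hz,
            "role": epochs.role, "block": epochs.block,
            "state": epochs.state, "subject": epochs.subject,
        },
    )


def peak_to_trough(
    waveform: AEPWaveform, window_ms=DEFAULT_P2T_WINDOW_MS
) -> float:
    """Max minus min of the waveform within the post-stimulus window."""
    lo, hi = window_ms
    if lo < waveform.t_ms[0] or hi > waveform.t_ms[-1]:
        raise ValueError("window outside epoch span")
    sel = (waveform.t_ms >= lo) & (waveform.t_ms <= hi)
    seg = waveform.amp_uv[sel]
    return float(seg.max() - seg.min())


def pointwise_ranksum_mask(
    epochs_a: AEPEpochSet,
    epochs_b: AEPEpochSet,
    alpha: float = 0.01,
    baseline_window=DEFAULT_BASELINE_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time-point two-sided Wilcoxon rank-sum comparison.

    Returns (mask, p_values); mask is True where p < alpha.  No correction
    for multiple comparisons is applied (exploratory, per-point ticks).
    Both sets must share a time axis and have at least 5 epochs each.
    """
    if len(epochs_a.t_ms) != len(epochs_b.t_ms) or not np.allclose(
        epochs_a.t_ms, epochs_b.t_ms
    ):
        raise ValueError("epoch sets have mismatched time axes")
    if epochs_a.n_epochs < 5 or epochs_b.n_epochs < 5:
        raise ValueError("rank-sum mask needs >= 5 epochs per group")
    a = _baseline_correct(epochs_a.epochs, epochs_a.t_ms, baseline_window)
    b = _baseline_correct(epochs_b.epochs, epochs_b.t_ms, baseline_window)
    res = stats.ranksums(a, b, axis=0)
    p = np.asarray(res.pvalue)
    return p < alpha, p


def mmn_index(
    aep_deviant: AEPWaveform,
    aep_standard: AEPWaveform,
    window_ms=DEFAULT_MMN_WINDOW_MS,
) -> tuple[AEPWaveform, float]:
    """Mismatch negativity: deviant minus standard for the same tone.

    Both waveforms must describe the same physical stimulus (equal dB and
    Hz) presented under different block roles.  Returns the difference
    waveform and the scalar index (mean difference within the window).
    """
    for key in ("tone_db", "tone_hz"):
        if aep_deviant.labels.get(key) != aep_standard.labels.get(key):
            raise ValueError(
                f"MMN requires identical physical stimuli (mismatched {key})"
            )
    if len(aep_deviant.t_ms) != len(aep_standard.t_ms) or not np.allclose(
        aep_deviant.t_ms, aep_standard.t_ms
    ):
        raise ValueError("waveforms have mismatched time axes")
    diff = AEPWaveform(
        t_ms=aep_deviant.t_ms.copy(),
        amp_uv=aep_deviant.amp_uv - aep_standard.amp_uv,
        n_trials=min(aep_deviant.n_trials, aep_standard.n_trials),
        labels={**aep_deviant.labels, "contrast": "deviant-standard"},
    )
    lo, hi = window_ms
    sel = (diff.t_ms >= lo) & (diff.t_ms <= hi)
    return diff, float(diff.amp_uv[sel].mean())
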