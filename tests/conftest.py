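import numpy as np
import pytest

from oculodecode.pipeline import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Small deterministic dataset: every task for each subject/state."""
    return make_fixtures(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_clean_trace(n=600, fs=500.0, x=None, y=None, tx=None, ty=None, pupil=None):
    """Bare EyeTrace with default-zero channels (helper for unit tests)."""
    from oculodecode.io import EyeTrace

    zeros = np.zeros(n)
    return EyeTrace(
        t_ms=np.arange(n) * 1000.0 / fs,
        x_deg=zeros.copy() if x is None else np.asarray(x, float),
        y_deg=zeros.copy() if y is None else np.asarray(y, float),
        pupil_au=np.full(n, 1000.0) if pupil is None else np.asarray(pupil, float),
        target_x_deg=zeros.copy() if tx is None else np.asarray(tx, float),
        target_y_deg=zeros.copy() if ty is None else np.asarray(ty, float),
        fs_hz=fs,
        events={"fixation_on": 0, "trial_end": n - 1},
    )


def inject_saccade(trace, onset_idx, amplitude, direction, ms_params=None, **kw):
    """Add a main-sequence saccade to a trace; returns its waveform."""
    from oculodecode.synth import MainSequenceParams, simulate_saccade

    ms = ms_params or MainSequenceParams()
    wf = simulate_saccade(amplitude, direction, ms, trace.fs_hz, **kw)
    m = min(wf.n, trace.n_samples - 1 - onset_idx)
    trace.x_deg[onset_idx + 1 : onset_idx + 1 + m] += wf.dx[:m]
    trace.y_deg[onset_idx + 1 : onset_idx + 1 + m] += wf.dy[:m]
    if onset_idx + 1 + m < trace.n_samples:
        trace.x_deg[onset_idx + 1 + m :] += wf.dx[m - 1]
        trace.y_deg[onset_idx + 1 + m :] += wf.dy[m - 1]
    return wf
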