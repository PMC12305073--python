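import numpy as np
import pytest

from oromotor.preprocess import DffTrace, preprocess_recording
from oromotor.synthetic import SessionParams, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One fully generated synthetic session with default (almond) parameters."""
    params = SessionParams(seed=3)
    photo, jaw, ann, truth = generate_session(params)
    return params, photo, jaw, ann, truth


@pytest.fixture(scope="session")
def default_dff(default_session):
    """Isosbestic-corrected dF/F of the default session."""
    _, photo, _, _, _ = default_session
    dff, fit, minima = preprocess_recording(photo)
    return dff, fit, minima


@pytest.fixture(scope="session")
def noiseless_session():
    """Session with measurement noise and motion off (pure signal + bleach)."""
    params = SessionParams(
        seed=5, noise_sd=0.0, motion_amp=0.0, jaw_noise_px=0.0, dropout_rate=0.0
    )
    photo, jaw, ann, truth = generate_session(params)
    return params, photo, jaw, ann, truth


def make_dff(x, fs=120.0, t0=0.0):
    x = np.asarray(x, dtype=float)
    return DffTrace(t=t0 + np.arange(len(x)) / fs, dff=x, fs=fs)
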