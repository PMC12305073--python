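"""Photometry preprocessing: decimation, baseline minima, isosbestic dF/F.

The raw 490 nm (calcium-dependent) and 405 nm (isosbestic) channels are
boxcar-averaged and subsampled, a local baseline is defined by rolling-
minimum candidates kept only during low-activity periods, the isosbestic
trace is regressed onto the signal at those baseline samples, and dF/F is
the residual of that regression normalized by the fitted baseline F:
``dff = (sig490 - F) / F`` with ``F = offset + scale * iso405``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBaselineError,
    NonpositiveBaselineError,
    ParameterError,
    SingularFitError,
)
from .synthetic import PhotometryRecording

__all__ = [
    "BaselineMinima",
    "IsosbesticFit",
    "DffTrace",
    "decimate_boxcar",
    "estimate_baseline_minima",
    "fit_isosbestic",
    "compute_dff",
    "preprocess_recording",
]


@dataclass
class BaselineMinima:
    """Retained local minima defining the low-activity baseline."""

    indices: np.ndarray
    times: np.ndarray
    values: np.ndarray


@dataclass
class IsosbesticFit:
    """Linear map from the isosbestic channel to the signal baseline."""

    offset: float
    scale: float
    fitted_f: np.ndarray
    r2: float


@dataclass
class DffTrace:
    """Isosbestic-corrected, normalized fluorescence."""

    t: np.ndarray
    dff: np.ndarray
    fs: float


def decimate_boxcar(raw: PhotometryRecording, factor: int) -> PhotometryRecording:
    """Boxcar-average disjoint blocks of ``factor`` samples and subsample.

    Output sampling rate is ``raw.fs / factor``; a trailing partial block is
    dropped, so the output has ``floor(N / factor)`` samples.
    """
    n = len(raw.t)
    if factor <= 0 or factor > n:
        raise ParameterError(f"factor must be in [1, {n}], got {factor}")
    m = n // factor

    def block_mean(x):
        return x[: m * factor].reshape(m, factor).mean(axis=1)

    return PhotometryRecording(
        t=block_mean(raw.t),
        sig490=block_mean(raw.sig490),
        iso405=block_mean(raw.iso405),
        fs=raw.fs / factor,
    )


def _enforce_min_gap(idx: list[int], values: np.ndarray, min_gap: int) -> list[int]:
    """While successive minima are closer than ``min_gap`` samples, keep the
    smaller-valued of the pair (ties: keep the earlier).  Violations are
    resolved left to right."""
    idx = list(idx)
    i = 0
    while i < len(idx) - 1:
        if idx[i + 1] - idx[i] < min_gap:
            if values[idx[i]] <= values[idx[i + 1]]:
                del idx[i + 1]
            else:
                del idx[i]
            if i > 0:
                i -= 1
        else:
            i += 1
    return idx


def estimate_baseline_minima(
    signal: np.ndarray,
    fs: float,
    window_s: float = 5.0,
    min_gap_samples: int = 100,
    low_activity_quantile: float = 0.5,
) -> BaselineMinima:
    """Locate baseline samples: rolling-minimum candidates, gap-pruned,
    restricted to low-activity periods.

    A sample is a candidate if it equals the rolling minimum over a centred
    ``window_s`` window (windows shrink at the trace edges).  Candidates
    closer than ``min_gap_samples`` are pruned keeping the smaller value.
    Finally, candidates whose surrounding-window SD exceeds the
    ``low_activity_quantile`` quantile of all windowed SDs are dropped;
    pass 1.0 to disable the activity gate.
    """
    x = np.asarray(signal, dtype=float)
    w = int(round(window_s * fs))
    if w < 1:
        raise ParameterError(f"window_s={window_s} is below one sample at fs={fs}")
    if len(x) <= w:
        raise ParameterError(f"signal length {len(x)} must exceed the {w}-sample window")
    if min_gap_samples < 1:
        raise ParameterError(f"min_gap_samples must be >= 1, got {min_gap_samples}")
    s = pd.Series(x)
    rmin = s.rolling(w, center=True, min_periods=1).min().to_numpy()
    candidates = np.flatnonzero(x == rmin)
    kept = _enforce_min_gap(candidates.tolist(), x, min_gap_samples)
    if low_activity_quantile < 1.0:
        act = s.rolling(w, center=True, min_periods=2).std().to_numpy()
        act = np.nan_to_num(act, nan=0.0)
        cut = np.quantile(act, low_activity_quantile)
        kept = [i for i in kept if act[i] <= cut]
    kept = np.asarray(kept, dtype=int)
    if kept.size < 2:
        raise DegenerateBaselineError(
            f"only {kept.size} baseline minima survived; isosbestic fit impossible"
        )
    return BaselineMinima(indices=kept, times=kept / fs, values=x[kept])


def fit_isosbestic(
    sig490: np.ndarray, iso405: np.ndarray, minima: BaselineMinima
) -> IsosbesticFit:
    """OLS of the signal on the isosbestic channel at the baseline minima.

    The fitted line evaluated on the full isosbestic trace is the baseline
    F used for dF/F normalization.
    """
    sig490 = np.asarray(sig490, dtype=float)
    iso405 = np.asarray(iso405, dtype=float)
    if len(sig490) != len(iso405):
        raise ParameterError("sig490 and iso405 must have equal lengths")
    idx = minima.indices
    if idx.size < 2:
        raise DegenerateBaselineError("need at least 2 minima for the regression")
    xi, yi = iso405[idx], sig490[idx]
    if np.ptp(xi) == 0:
        raise SingularFitError("isosbestic channel is constant at the baseline minima")
    scale, offset = np.polyfit(xi, yi, 1)
    pred = offset + scale * xi
    ss_res = float(np.sum((yi - pred) ** 2))
    ss_tot = float(np.sum((yi - yi.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return IsosbesticFit(
        offset=float(offset),
        scale=float(scale),
        fitted_f=offset + scale * iso405,
        r2=r2,
    )


def compute_dff(
    sig490: np.ndarray, fit: IsosbesticFit, t: np.ndarray | None = None, fs: float = 1.0
) -> DffTrace:
    """``dff = (sig490 - F) / F`` with F the scaled isosbestic regression."""
    sig490 = np.asarray(sig490, dtype=float)
    f = fit.fitted_f
    if len(f) != len(sig490):
        raise ParameterError("fitted_f length does not match sig490")
    bad = np.flatnonzero(f <= 0)
    if bad.size:
        raise NonpositiveBaselineError(
            f"fitted baseline F <= 0 at samples {bad[0]}..{bad[-1]} ({bad.size} samples)"
        )
    if t is None:
        t = np.arange(len(sig490)) / fs
    return DffTrace(t=np.asarray(t, dtype=float), dff=(sig490 - f) / f, fs=fs)


def preprocess_recording(
    raw: PhotometryRecording,
    decimate_factor: int = 1,
    window_s: float = 5.0,
    min_gap_samples: int = 100,
    low_activity_quantile: float = 0.5,
) -> tuple[DffTrace, IsosbesticFit, BaselineMinima]:
    """Full preprocessing chain from a raw recording to a dF/F trace."""
    rec = decimate_boxcar(raw, decimate_factor) if decimate_factor > 1 else raw
    minima = estimate_baseline_minima(
        rec.sig490,
        rec.fs,
        window_s=window_s,
        min_gap_samples=min_gap_samples,
        low_activity_quantile=low_activity_quantile,
    )
    fit = fit_isosbestic(rec.sig490, rec.iso405, minima)
    dff = compute_dff(rec.sig490, fit, t=rec.t, fs=rec.fs)
    return dff, fit, minima
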