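"""Jaw-pose kinematics: calibration, smoothing, closure onsets, displacement.

The vertical jaw coordinate from markerless tracking is calibrated against
the 1.25 mm fiber-optic ferrule, low-confidence frames are interpolated and
the trace Savitzky-Golay smoothed.  Closure onsets are peaks of the first
derivative in the closing direction separated by at least 40 ms; the
peri-stimulation displacement is the mean position 50-500 ms into the laser
pulse relative to the maximal open position 550-50 ms before it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import ParameterError, QualityError, RangeError
from .stats import TestReport, gated_group_comparison  # noqa: F401  (re-exported)
from .synthetic import JawTrace

__all__ = [
    "CalibrationResult",
    "OnsetSet",
    "DisplacementResult",
    "calibrate",
    "preprocess_jaw",
    "detect_closure_onsets",
    "stim_displacement",
    "gated_group_comparison",
]

FERRULE_MM = 1.25


@dataclass
class CalibrationResult:
    """Pixel-to-millimetre conversion from the ferrule diameter."""

    mm_per_px: float
    ferrule_mm: float
    ferrule_px: float


@dataclass
class OnsetSet:
    """Detected jaw-closure onsets."""

    onset_times: np.ndarray
    min_gap_s: float
    window_s: float


@dataclass
class DisplacementResult:
    """Peri-stimulation jaw displacement.

    Positive displacement = more closed than the pre-stimulation maximal
    open reference; negative = more open.
    """

    displacement: float
    stim_onset_s: float
    reference_max_open: float
    units: str


def calibrate(ferrule_px: float, ferrule_mm: float = FERRULE_MM) -> CalibrationResult:
    """mm-per-pixel factor from the imaged ferrule diameter."""
    if ferrule_px <= 0:
        raise ParameterError(f"ferrule_px must be > 0, got {ferrule_px}")
    return CalibrationResult(
        mm_per_px=ferrule_mm / ferrule_px, ferrule_mm=ferrule_mm, ferrule_px=ferrule_px
    )


def preprocess_jaw(
    jaw: JawTrace,
    sg_window: int = 11,
    sg_order: int = 3,
    min_confidence: float = 0.9,
    calibration: CalibrationResult | None = None,
    max_bad_fraction: float = 0.2,
) -> JawTrace:
    """Interpolate low-confidence frames, smooth, optionally calibrate to mm."""
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ParameterError(
            f"sg_window must be odd and > sg_order, got window={sg_window} order={sg_order}"
        )
    pos = np.asarray(jaw.pos, dtype=float).copy()
    conf = np.asarray(jaw.confidence, dtype=float)
    bad = conf < min_confidence
    frac = bad.mean()
    if frac > max_bad_fraction:
        raise QualityError(
            f"{frac:.1%} of frames below confidence {min_confidence}; "
            f"limit is {max_bad_fraction:.0%}"
        )
    if bad.any():
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise QualityError("no frames above the confidence threshold")
        pos[bad] = np.interp(np.flatnonzero(bad), good, pos[good])
    pos = savgol_filter(pos, sg_window, sg_order)
    units = jaw.units
    if calibration is not None:
        pos = pos * calibration.mm_per_px
        units = "mm"
    return replace(jaw, pos=pos, units=units)


def _noise_mad(closing: np.ndarray) -> float:
    """Robust high-frequency noise scale of the closing-velocity trace."""
    d = np.diff(closing)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def detect_closure_onsets(
    jaw: JawTrace,
    windows: list[tuple[float, float]] | None = None,
    window_s: float = 5.0,
    min_gap_s: float = 0.040,
    prominence_sd: float = 3.0,
    opening_sign: int = 1,
) -> OnsetSet:
    """Peaks of the closing-direction jaw velocity, 40 ms apart minimum.

    Within each analysis window, local maxima of the first derivative in the
    closing direction whose prominence exceeds ``prominence_sd`` times the
    robust noise scale of the velocity trace are collected; onsets are then
    retained greedily largest-first subject to the ``min_gap_s`` separation.

    Parameters
    ----------
    windows : list of (start_s, end_s), optional
        Analysis windows (e.g. chewing bouts); by default the trace is
        partitioned into consecutive ``window_s`` windows.
    opening_sign : {1, -1}
        +1 if an increasing coordinate means jaw opening (video geometry
        dependent).
    """
    t = jaw.t
    pos = np.asarray(jaw.pos, dtype=float)
    closing = -opening_sign * np.gradient(pos, 1.0 / jaw.fs)
    if windows is None:
        starts = np.arange(t[0], t[-1], window_s)
        windows = [(float(s), float(min(s + window_s, t[-1]))) for s in starts]
    peaks_t, peaks_h = [], []
    for s, e in windows:
        if s < t[0] - 0.5 / jaw.fs or e > t[-1] + 0.5 / jaw.fs:
            raise RangeError(f"window ({s}, {e}) outside trace [{t[0]:.3f}, {t[-1]:.3f}]")
        m = (t >= s) & (t <= e)
        c = closing[m]
        if c.size < 3:
            continue
        floor = prominence_sd * _noise_mad(c)
        idx, _ = find_peaks(c, prominence=max(floor, 1e-12))
        peaks_t.extend(t[m][idx])
        peaks_h.extend(c[idx])
    peaks_t = np.asarray(peaks_t)
    peaks_h = np.asarray(peaks_h)
    kept: list[float] = []
    for i in np.argsort(peaks_h)[::-1]:  # largest first
        ti = peaks_t[i]
        if all(abs(ti - k) >= min_gap_s for k in kept):
            kept.append(float(ti))
    return OnsetSet(onset_times=np.sort(kept), min_gap_s=min_gap_s, window_s=window_s)


def stim_displacement(
    jaw: JawTrace,
    stim_onset_s: float,
    post_window: tuple[float, float] = (0.05, 0.5),
    pre_window: tuple[float, float] = (-0.55, -0.05),
    opening_sign: int = 1,
    mode: str = "difference",
) -> DisplacementResult:
    """Jaw displacement during stimulation relative to the maximal open position.

    Mean position over ``stim + post_window`` relative to the extremum in
    the opening direction over ``stim + pre_window``.  ``mode='ratio'``
    divides by the reference instead of subtracting.
    """
    t = jaw.t
    o = opening_sign * np.asarray(jaw.pos, dtype=float)  # openness
    pre_lo, pre_hi = stim_onset_s + pre_window[0], stim_onset_s + pre_window[1]
    post_lo, post_hi = stim_onset_s + post_window[0], stim_onset_s + post_window[1]
    half = 0.5 / jaw.fs
    if pre_lo < t[0] - half or post_hi > t[-1] + half:
        raise RangeError(
            f"stimulation windows [{pre_lo:.3f}, {post_hi:.3f}] outside trace"
        )
    pre = o[(t >= pre_lo) & (t <= pre_hi)]
    post = o[(t >= post_lo) & (t <= post_hi)]
    if pre.size == 0 or post.size == 0:
        raise RangeError("empty pre- or post-stimulation window")
    ref = float(pre.max())
    if mode == "difference":
        disp = ref - float(post.mean())
    elif mode == "ratio":
        if ref == 0:
            raise ParameterError("ratio mode undefined for zero reference")
        disp = float(post.mean()) / ref
    else:
        raise ParameterError(f"mode must be 'difference' or 'ratio', got {mode!r}")
    return DisplacementResult(
        displacement=disp,
        stim_onset_s=stim_onset_s,
        reference_max_open=ref,
        units=jaw.units,
    )
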