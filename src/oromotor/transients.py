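"""Calcium-transient detection and bite-offset histograms.

Transient onsets are detected on the dF/F trace after removing the chewing
band (zero-phase band-stop, 2-8 Hz): the delayed difference
``d[i] = x[i] - x[i - round(delay * fs)]`` approximates the rate of rise at
the indicator's timescale, onsets are upward crossings of the
mean + k*SD threshold of that difference, and crossings within a 0.4 s
refractory period of a retained onset are discarded (the indicator cannot
resolve faster event pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ParameterError
from .preprocess import DffTrace

__all__ = ["TransientSet", "OffsetHistogram", "detect_transients", "transient_bite_histogram", "average_histograms"]


@dataclass
class TransientSet:
    """Detected transient onsets with the detection settings used."""

    onset_times: np.ndarray
    threshold: float
    delay_s: float


@dataclass
class OffsetHistogram:
    """Transients per bite in 200 ms offset bins spanning -10..+10 s."""

    bin_edges: np.ndarray
    probability: np.ndarray
    n_bites: int


def detect_transients(
    dff: DffTrace,
    delay_s: float = 0.100,
    k_sd: float = 2.0,
    refractory_s: float = 0.4,
    notch_band: tuple[float, float] = (2.0, 8.0),
    span: tuple[float, float] | None = None,
) -> TransientSet:
    """Detect calcium-transient onsets on a dF/F trace.

    Parameters
    ----------
    dff : DffTrace
        Input trace.
    delay_s : float
        Delay of the difference operator; the per-session rise-time range is
        75-125 ms.
    k_sd : float
        Threshold in SDs above the mean of the delayed difference.
    refractory_s : float
        Minimum separation between retained onsets (keep-first).
    notch_band : (low, high) Hz
        Band removed before differencing (suppresses the chewing rhythm).
    span : (start_s, end_s), optional
        Restrict both the threshold statistics and the detection to this
        interval; default is the full trace.
    """
    if not (0.075 <= delay_s <= 0.125):
        raise ParameterError(
            f"delay_s must lie in the rise-time range [0.075, 0.125] s, got {delay_s}"
        )
    t, x, fs = dff.t, np.asarray(dff.dff, dtype=float), dff.fs
    if span is not None:
        m = (t >= span[0]) & (t <= span[1])
        t, x = t[m], x[m]
    k = int(round(delay_s * fs))
    if k < 1:
        raise ParameterError(f"delay_s={delay_s} is below one sample at fs={fs}")
    if len(x) <= k:
        raise ParameterError("trace too short for the requested delay")

    sos = butter(4, notch_band, btype="bandstop", fs=fs, output="sos")
    xf = sosfiltfilt(sos, x)

    d = xf[k:] - xf[:-k]  # d[j] belongs to sample j + k
    sd = float(np.std(d))
    if sd == 0:
        warnings.warn("flat dF/F trace: no transients detectable", stacklevel=2)
        return TransientSet(onset_times=np.empty(0), threshold=float(np.mean(d)), delay_s=delay_s)
    theta = float(np.mean(d) + k_sd * sd)

    above = d > theta
    cross = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    onset_idx = cross + k  # index into x/t
    kept = []
    last = -np.inf
    for i in onset_idx:
        ti = t[i]
        if ti - last >= refractory_s:
            kept.append(ti)
            last = ti
    return TransientSet(onset_times=np.asarray(kept), threshold=theta, delay_s=delay_s)


def transient_bite_histogram(
    transients: TransientSet | np.ndarray,
    bite_onsets: np.ndarray,
    window_s: tuple[float, float] = (-10.0, 10.0),
    bin_s: float = 0.2,
) -> OffsetHistogram:
    """Probability of a transient per bite onset in offset bins.

    For every (bite, transient) pair whose offset ``transient - bite`` falls
    in ``window_s`` the half-open bin ``[edge, edge + bin_s)`` is
    incremented; counts are normalized by the number of bites.
    """
    times = transients.onset_times if isinstance(transients, TransientSet) else np.asarray(transients)
    bites = np.asarray(bite_onsets, dtype=float)
    if bites.size == 0:
        raise ParameterError("histogram normalization undefined with zero bites")
    lo, hi = window_s
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for b in bites:
        off = times - b
        off = off[(off >= lo) & (off < lo + n_bins * bin_s)]
        if off.size:
            which = np.floor((off - lo) / bin_s).astype(int)
            np.add.at(counts, which, 1.0)
    return OffsetHistogram(
        bin_edges=edges, probability=counts / bites.size, n_bites=int(bites.size)
    )


def average_histograms(hists: list[OffsetHistogram]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and SD of per-session offset histograms (edges must match)."""
    if not hists:
        raise ParameterError("no histograms to average")
    edges = hists[0].bin_edges
    for h in hists[1:]:
        if not np.array_equal(h.bin_edges, edges):
            raise ParameterError("histogram bin edges differ across sessions")
    mat = np.vstack([h.probability for h in hists])
    return edges, mat.mean(axis=0), mat.std(axis=0, ddof=1) if len(hists) > 1 else np.zeros(len(edges) - 1)
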