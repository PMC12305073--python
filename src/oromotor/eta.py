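"""Bite-triggered averaging of dF/F with a resampled-timestamp bootstrap.

Segments spanning 1 s before to 4 s after each event are extracted on the
dF/F sample grid (nearest sample to the event time), each baseline-corrected
by its own pre-event [-1, 0) s mean, then averaged with SEM.  The null
reference repeats the procedure with event timestamps redrawn uniformly
within the observed event range (100 iterations by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .preprocess import DffTrace

__all__ = ["ETAResult", "ETABootstrap", "event_triggered_average", "bootstrap_eta"]


@dataclass
class ETAResult:
    """Event-triggered average with per-trial segments."""

    t_rel: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_trials: int
    per_trial: np.ndarray
    n_dropped: int = 0


@dataclass
class ETABootstrap:
    """Null ETA from uniformly resampled event timestamps."""

    boot_mean: np.ndarray
    boot_sd: np.ndarray
    boot_sem: np.ndarray
    n_iterations: int
    seed: int


def _segments(
    x: np.ndarray, t: np.ndarray, fs: float, events: np.ndarray, n_pre: int, n_post: int
) -> tuple[np.ndarray, int]:
    centers = np.round((np.asarray(events, dtype=float) - t[0]) * fs).astype(int)
    ok = (centers - n_pre >= 0) & (centers + n_post < len(x))
    dropped = int((~ok).sum())
    centers = centers[ok]
    if centers.size == 0:
        raise InsufficientDataError("no event has a full [-pre, +post] window in the recording")
    idx = centers[:, None] + np.arange(-n_pre, n_post + 1)[None, :]
    seg = x[idx]
    base = seg[:, :n_pre].mean(axis=1)  # [-1, 0) s: pre-event samples only
    return seg - base[:, None], dropped


def event_triggered_average(
    dff: DffTrace, events, pre_s: float = 1.0, post_s: float = 4.0
) -> ETAResult:
    """Baseline-corrected mean dF/F aligned to event onsets.

    Events whose window is truncated by the recording edges are dropped
    (count reported in ``n_dropped``).
    """
    if pre_s <= 0 or post_s <= 0:
        raise ParameterError("pre_s and post_s must be > 0")
    x = np.asarray(dff.dff, dtype=float)
    n_pre = int(round(pre_s * dff.fs))
    n_post = int(round(post_s * dff.fs))
    seg, dropped = _segments(x, dff.t, dff.fs, np.asarray(events, dtype=float), n_pre, n_post)
    t_rel = np.arange(-n_pre, n_post + 1) / dff.fs
    mean = seg.mean(axis=0)
    if seg.shape[0] > 1:
        sem = seg.std(axis=0, ddof=1) / np.sqrt(seg.shape[0])
    else:
        sem = np.zeros_like(mean)
    return ETAResult(
        t_rel=t_rel, mean=mean, sem=sem, n_trials=seg.shape[0], per_trial=seg, n_dropped=dropped
    )


def bootstrap_eta(
    dff: DffTrace,
    events,
    n_iter: int = 100,
    seed: int = 0,
    pre_s: float = 1.0,
    post_s: float = 4.0,
) -> ETABootstrap:
    """Null ETA by redrawing event timestamps uniformly in the observed range.

    Each iteration draws ``len(events)`` timestamps from
    ``Uniform(min(events), max(events))``, recomputes the baseline-corrected
    ETA, and the per-lag mean/SD/SEM across iterations are returned.
    Deterministic for a given seed.
    """
    events = np.asarray(events, dtype=float)
    if events.size < 2 or np.ptp(events) == 0:
        raise InsufficientDataError("bootstrap needs >= 2 distinct event times")
    rng = np.random.default_rng(seed)
    lo, hi = float(events.min()), float(events.max())
    means = []
    for _ in range(n_iter):
        fake = rng.uniform(lo, hi, events.size)
        res = event_triggered_average(dff, fake, pre_s=pre_s, post_s=post_s)
        means.append(res.mean)
    mat = np.vstack(means)
    return ETABootstrap(
        boot_mean=mat.mean(axis=0),
        boot_sd=mat.std(axis=0, ddof=1),
        boot_sem=mat.std(axis=0, ddof=1) / np.sqrt(n_iter),
        n_iterations=n_iter,
        seed=seed,
    )
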