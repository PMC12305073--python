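"""Time-frequency analysis of dF/F during ingestion.

The chewing rhythm appears as a narrow band near 5 Hz in the dF/F signal.
Analysis proceeds on ~20 s consumption segments: high-pass at 3 Hz, complex
Morlet continuous wavelet transform (center frequency 3.0, bandwidth 3.0)
on a 3-10 Hz grid, per-animal scaling of scalogram magnitudes to the global
min/max across both food conditions, extraction of the per-timepoint
dominant frequency gated at 40% of the segment's maximum amplitude, Gaussian
KDE (bandwidth 0.2 Hz) summarization, and a linear mixed model comparing the
spread of the dominant-frequency distribution between food conditions with
trial as a random effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import stats as sps
from scipy.signal import butter, sosfiltfilt

from .errors import InsufficientDataError, PairingError, ParameterError, RangeError
from .preprocess import DffTrace
from .stats import TestReport
from .synthetic import BehaviorAnnotations, JawTrace

__all__ = [
    "Scalogram",
    "DominantFrequencySeries",
    "FrequencySummary",
    "PhaseResult",
    "compute_scalogram",
    "apply_global_scaling",
    "dominant_frequency_series",
    "frequency_kde_sd",
    "compare_conditions",
    "time_fraction_comparison",
    "jaw_dff_phase",
]

DEFAULT_WAVELET = "cmor3.0-3.0"
FBAND = (3.0, 10.0)
FREQ_STEP = 0.05


@dataclass
class Scalogram:
    """CWT magnitude over a 3-10 Hz grid for one segment."""

    freqs: np.ndarray
    t: np.ndarray
    magnitude: np.ndarray  # (n_freqs, n_times)
    scaling: tuple[float, float] | None = None  # (global_min, global_max)

    @property
    def scaled(self) -> np.ndarray:
        """Magnitude mapped to [0, 1] by the stored global scaling."""
        if self.scaling is None:
            raise ParameterError("scalogram has no global scaling; call apply_global_scaling")
        lo, hi = self.scaling
        if hi <= lo:
            return np.zeros_like(self.magnitude)
        return np.clip((self.magnitude - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class DominantFrequencySeries:
    """Per-timepoint argmax frequency with the low-amplitude gate applied."""

    t: np.ndarray
    f_dom: np.ndarray  # NaN where masked
    peak_amp: np.ndarray
    mask: np.ndarray  # True = discarded (low amplitude)
    gate_fraction: float

    @property
    def unmasked(self) -> np.ndarray:
        return self.f_dom[~self.mask]


@dataclass
class FrequencySummary:
    """Per-segment summary of the dominant-frequency distribution."""

    kde_grid: np.ndarray
    kde_density: np.ndarray
    sd_dom: float
    mean_peak_amp: float
    mean_peak_freq: float
    condition: str = ""
    trial_id: str = ""
    n_samples: int = 0


@dataclass
class PhaseResult:
    """Cross-correlation lag between jaw displacement and dF/F oscillation."""

    lag_s: float | None
    peak_corr: float
    n_samples: int


def compute_scalogram(
    dff: DffTrace,
    segment: tuple[float, float],
    highpass_hz: float = 3.0,
    wavelet: str = DEFAULT_WAVELET,
    fband: tuple[float, float] = FBAND,
    freq_step: float = FREQ_STEP,
) -> Scalogram:
    """Complex-Morlet CWT magnitude of a high-passed dF/F segment.

    The frequency grid spans ``fband`` in ``freq_step`` increments and the
    scale of each row follows from the wavelet's center frequency.
    """
    t, x, fs = dff.t, np.asarray(dff.dff, dtype=float), dff.fs
    s0, s1 = segment
    if s0 < t[0] - 0.5 / fs or s1 > t[-1] + 0.5 / fs or s1 <= s0:
        raise RangeError(f"segment {segment} outside recording [{t[0]:.3f}, {t[-1]:.3f}]")
    if fs <= 2 * fband[1]:
        raise ParameterError(f"fs={fs} must exceed twice the upper band edge {fband[1]}")
    m = (t >= s0) & (t <= s1)
    seg_t, seg_x = t[m], x[m]
    sos = butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    seg_x = sosfiltfilt(sos, seg_x)
    freqs = np.arange(fband[0], fband[1] + freq_step / 2, freq_step)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    coef, _ = pywt.cwt(seg_x, scales, wavelet, sampling_period=1.0 / fs)
    return Scalogram(freqs=freqs, t=seg_t, magnitude=np.abs(coef))


def apply_global_scaling(scalograms: list[Scalogram]) -> list[Scalogram]:
    """Attach the shared (min, max) scaling across a set of scalograms.

    The set must contain segments from both food conditions of one animal:
    the published normalization is per animal across conditions, so callers
    assemble the list accordingly.
    """
    if not scalograms:
        raise ParameterError("no scalograms to scale")
    lo = min(float(s.magnitude.min()) for s in scalograms)
    hi = max(float(s.magnitude.max()) for s in scalograms)
    for s in scalograms:
        s.scaling = (lo, hi)
    return scalograms


def dominant_frequency_series(
    scal: Scalogram, gate_fraction: float = 0.4
) -> DominantFrequencySeries:
    """Per-timepoint dominant frequency, gated by wavelet amplitude.

    ``f_dom(t)`` is the frequency of maximal magnitude at each time point
    (ties resolved toward the lower frequency); points whose peak amplitude
    falls below ``gate_fraction`` of the segment's maximum are masked.
    """
    mag = scal.magnitude
    imax = np.argmax(mag, axis=0)  # first (= lowest-frequency) maximum
    cols = np.arange(mag.shape[1])
    peak = mag[imax, cols]
    gmax = float(mag.max()) if mag.size else 0.0
    mask = peak < gate_fraction * gmax
    f_dom = scal.freqs[imax].astype(float)
    f_dom[mask] = np.nan
    return DominantFrequencySeries(
        t=scal.t, f_dom=f_dom, peak_amp=peak, mask=mask, gate_fraction=gate_fraction
    )


def frequency_kde_sd(
    dom: DominantFrequencySeries,
    bandwidth: float = 0.2,
    condition: str = "",
    trial_id: str = "",
    grid: np.ndarray | None = None,
) -> FrequencySummary:
    """Gaussian-KDE summary of the unmasked dominant frequencies.

    ``sd_dom`` is the SD of the unmasked values; the KDE uses an absolute
    Gaussian bandwidth in Hz.  ``mean_peak_amp``/``mean_peak_freq`` average
    the gated peak amplitude and frequency over the segment.
    """
    vals = dom.unmasked
    if vals.size < 10:
        raise InsufficientDataError(f"only {vals.size} unmasked samples; need >= 10")
    if grid is None:
        grid = np.arange(FBAND[0] - 1.0, FBAND[1] + 1.0 + 1e-9, 0.01)
    dens = sps.norm.pdf((grid[:, None] - vals[None, :]) / bandwidth).mean(axis=1) / bandwidth
    return FrequencySummary(
        kde_grid=grid,
        kde_density=dens,
        sd_dom=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        mean_peak_amp=float(np.mean(dom.peak_amp[~dom.mask])),
        mean_peak_freq=float(np.mean(vals)),
        condition=condition,
        trial_id=trial_id,
        n_samples=int(vals.size),
    )


def compare_conditions(summaries: list[FrequencySummary]) -> TestReport:
    """Mixed-model comparison of dominant-frequency SD between conditions.

    Fits ``sd_dom ~ condition`` with a random intercept per trial.  If the
    random-effects structure is singular or the fit fails, falls back to an
    OLS condition-only model with a warning.
    """
    df = pd.DataFrame(
        {
            "sd_dom": [s.sd_dom for s in summaries],
            "condition": [s.condition for s in summaries],
            "trial": [s.trial_id for s in summaries],
        }
    )
    conds = sorted(df["condition"].unique())
    if len(conds) != 2:
        raise ParameterError(f"need exactly 2 conditions, got {conds}")
    for c in conds:
        if (df["condition"] == c).sum() < 2:
            raise InsufficientDataError(f"condition {c!r} has fewer than 2 segments")
    if np.ptp(df["sd_dom"].to_numpy()) == 0:
        return TestReport(
            method="degenerate (constant response)",
            statistic=0.0,
            pvalue=1.0,
            estimate=0.0,
            se=0.0,
            n=len(df),
        )
    import statsmodels.formula.api as smf

    term = f"condition[T.{conds[1]}]"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm("sd_dom ~ condition", df, groups=df["trial"]).fit(reml=True)
        if not np.isfinite(res.pvalues[term]):
            raise ValueError("non-finite mixed-model p-value")
        return TestReport(
            method="linear mixed model (trial random intercept)",
            statistic=float(res.tvalues[term]),
            pvalue=float(res.pvalues[term]),
            estimate=float(res.params[term]),
            se=float(res.bse[term]),
            n=len(df),
        )
    except Exception:
        warnings.warn(
            "mixed model singular or failed; falling back to condition-only OLS",
            stacklevel=2,
        )
        res = smf.ols("sd_dom ~ condition", df).fit()
        return TestReport(
            method="OLS fallback (no random effect)",
            statistic=float(res.tvalues[term]),
            pvalue=float(res.pvalues[term]),
            estimate=float(res.params[term]),
            se=float(res.bse[term]),
            n=len(df),
        )


def _epoch_time(epochs) -> float:
    return float(sum(e - s for s, e, *_ in epochs))


def chew_fraction(ann: BehaviorAnnotations) -> float:
    """Fraction of ingestion time spent chewing: chew / (chew + bite)."""
    chew = _epoch_time(ann.chew_epochs)
    bite = _epoch_time(ann.bite_epochs)
    if chew + bite == 0:
        raise InsufficientDataError("no chew or bite epochs annotated")
    return chew / (chew + bite)


def time_fraction_comparison(
    cond_a: list[BehaviorAnnotations], cond_b: list[BehaviorAnnotations]
) -> TestReport:
    """Paired Wilcoxon signed-rank on per-trial chewing fractions.

    Trials are matched by position across the two condition lists (the
    pooled-trials design: the same animals contribute matched trials to each
    food type).
    """
    if len(cond_a) != len(cond_b):
        raise PairingError(
            f"matched trials required: {len(cond_a)} vs {len(cond_b)} annotations"
        )
    fa = np.array([chew_fraction(a) for a in cond_a])
    fb = np.array([chew_fraction(b) for b in cond_b])
    d = fa - fb
    if np.all(d == 0):
        return TestReport(
            method="degenerate (all differences zero)",
            statistic=0.0,
            pvalue=1.0,
            estimate=0.0,
            se=0.0,
            n=len(d),
        )
    res = sps.wilcoxon(fa, fb, alternative="two-sided")
    return TestReport(
        method="Wilcoxon signed-rank",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        estimate=float(np.mean(d)),
        se=float(np.std(d, ddof=1) / np.sqrt(d.size)),
        n=len(d),
    )


def jaw_dff_phase(
    dff: DffTrace,
    jaw: JawTrace,
    chew_epochs,
    max_lag_s: float = 0.25,
    band: tuple[float, float] = (3.0, 10.0),
    min_corr: float = 0.2,
) -> PhaseResult:
    """Lag of peak normalized cross-correlation between jaw and dF/F rhythms.

    Both signals are band-passed to the chewing band on the dF/F time grid
    and correlated within the chew epochs over lags of +/- ``max_lag_s``.
    Positive lag means the jaw leads the calcium signal.  If the peak
    |correlation| stays below ``min_corr`` the lag is reported as undefined
    (``None``).
    """
    total = _epoch_time(chew_epochs)
    if total < 2.0:
        raise InsufficientDataError(f"chew epochs total {total:.2f} s; need >= 2 s")
    t, fs = dff.t, dff.fs
    jaw_i = np.interp(t, jaw.t, np.asarray(jaw.pos, dtype=float))
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    a = sosfiltfilt(sos, np.asarray(dff.dff, dtype=float))
    b = sosfiltfilt(sos, jaw_i)
    in_epoch = np.zeros(len(t), dtype=bool)
    for s, e, *_ in chew_epochs:
        in_epoch |= (t >= s) & (t <= e)
    max_shift = int(round(max_lag_s * fs))
    lags = np.arange(-max_shift, max_shift + 1)
    corrs = np.empty(len(lags))
    for j, lag in enumerate(lags):
        # correlate a[t] with b[t - lag]
        if lag >= 0:
            va, vb, vm = a[lag:], b[: len(b) - lag], in_epoch[lag:]
        else:
            va, vb, vm = a[:lag], b[-lag:], in_epoch[:lag]
        va, vb = va[vm], vb[vm]
        if va.size < 10 or np.std(va) == 0 or np.std(vb) == 0:
            corrs[j] = 0.0
        else:
            corrs[j] = np.corrcoef(va, vb)[0, 1]
    # near-periodic signals repeat their correlation peak every cycle; among
    # near-equal maxima report the lag closest to zero
    amax = float(np.max(np.abs(corrs)))
    near = np.flatnonzero(np.abs(corrs) >= 0.995 * amax)
    jbest = int(near[np.argmin(np.abs(lags[near]))])
    peak = float(corrs[jbest])
    lag_s = lags[jbest] / fs
    if abs(peak) < min_corr:
        return PhaseResult(lag_s=None, peak_corr=peak, n_samples=int(in_epoch.sum()))
    return PhaseResult(lag_s=float(lag_s), peak_corr=peak, n_samples=int(in_epoch.sum()))
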