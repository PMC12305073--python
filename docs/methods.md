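# Methods

This note documents the models, parameter choices and numerical conventions
behind `oromotor`, and what the synthetic benchmark does and does not
establish about real recordings.

## Synthetic sessions

A session emulates a head-fixed ingestion experiment on a 100 s timeline: a
lapping bout (licks at 7 Hz for 4 s, starting at 1 s), a quiet gap, then an
ingestion phase in which bites alternate with chewing epochs, followed by a
quiet tail. The quiet stretches before and after ingestion matter: the
baseline estimator needs uncontaminated low-activity windows, exactly as in
real sessions where analysis spans include pauses around consumption.

**Photometry.** `sig490 = B(t)·(1 + m(t)) + B(t)·e(t) + σ·ε(t)` and
`iso405 = c·[B(t)·(1 + m(t)) + σ·ε'(t)]`, where `B(t) = F0·exp(−t/τ_b)` is
the bleaching trend, `m(t)` a slow multiplicative motion artifact (Gaussian
noise low-passed at 0.5 Hz, 1% RMS by default) shared between channels, and
`e(t)` the calcium event term in ΔF/F units, present only in the signal
channel. The event term rides on the bleaching trend rather than being a
fixed additive waveform so that its ΔF/F amplitude is stationary — under
bleaching, an amplitude-fixed additive event would drift in ΔF/F terms and
no amplitude recovery statement could hold.

`e(t)` is the sum of:

- **bite transients** — a difference-of-exponentials kernel with 100 ms rise
  (the midpoint of the detector's 75–125 ms per-session delay range) and
  1.5 s decay, typical of the slow indicator family used for these
  recordings; unit peak scaled to `bite_dff_amp` (default 0.05 ΔF/F);
- **the chewing oscillation** — a raised cosine `amp/2 · (1 − cos φ(t))`
  inside each chew epoch with peaks at `chew_dff_amp` (default 0.02) and
  instantaneous frequency `f(t)` around `chew_freq_hz` (default 5.23 Hz),
  wandering as a piecewise-linear profile with knots every 0.5 s
  (SD 0.15 Hz for almond, 0.45 Hz for pasta, encoding the less regular
  pasta rhythm). The phase is the exact integral of the profile, so the
  photometry and jaw traces share one coherent oscillation;
- **a small tonic elevation** (0.01 ΔF/F) during the lapping bout.

Food types differ in epoch statistics: almond sessions have 20 bites and
chew epochs of mean 2.5 s; pasta sessions have 32 bites with mean 1.0 s
epochs — more frequent biting, scarcer and shorter chewing.

Defaults for unstated physical scales were chosen once on realism grounds:
`bleach_tau_s = 600 s` (mild bleaching over ~100 s; strong bleaching would
also leave a centered rolling-minimum rule without interior candidates on a
noise-free trace), and `noise_sd = 0.001` ΔF/F. The noise floor deserves a
note: the transient detector thresholds the delayed difference at
mean + 2 SD, so it only achieves a near-zero false-positive rate when the
event term dominates SD(d). The crossing-rate arithmetic puts that break-even
near a 0.0015 ΔF/F white-noise floor for the default event density; bulk
recordings with clean bite-locked transients therefore imply a noise floor at
or below ~0.001, which is what the generator emulates. At a floor of 0.003
or above, any implementation of this detector fires about once per second on
quiescent data.

**Jaw trace.** A single vertical coordinate (increasing = opening), resting
at 200 px with a 100 px chewing oscillation sharing the photometry phase, a
250 px single-cycle excursion per bite, a 40 px lick oscillation, 0.5 px
tracking noise, and 1% tracking dropouts (wild position, low likelihood).
The ferrule calibration (1.25 mm ≈ 125 px) gives 0.01 mm/px. True closure
onsets — the phase points of peak closing velocity, φ ≡ 3π/2 (mod 2π) — are
recorded in the ground truth.

**What the generator does not emulate:** hemodynamic or pH artifacts with
channel-specific dynamics, non-stationary noise, tongue/spout interactions,
chewing-side alternation, and optogenetically evoked jaw movement (laser
trains are generated as annotations only; their motor effect is a scenario
for the caller). Passing recovery tests on these sessions shows the
algorithms are correctly implemented and calibrated for rhythm frequencies,
amplitudes and event rates in the physiological range — not that they are
robust to every artifact class in real data.

## Preprocessing conventions

- Decimation blocks are non-overlapping, left-aligned means; a trailing
  partial block is dropped.
- The rolling-minimum window is specified in seconds and converted with the
  actual sampling rate (rounded to the nearest sample), since the recorded
  rate (120.48 Hz) makes fixed sample counts ambiguous. Windows shrink at
  the trace edges, so endpoints can be candidates; even-length windows lean
  one sample left, following the rolling conventions of the dataframe
  library used.
- Close-minima pruning resolves violations left to right, keeping the
  smaller value; equal values keep the earlier sample.
- "Low activity" is operationalized as a windowed SD at or below the 50th
  percentile of all windowed SDs (`low_activity_quantile`, configurable;
  1.0 disables the gate).
- The isosbestic fit is a single-pass OLS (`numpy.polyfit` degree 1) at the
  minima; no robust refit iteration.
- With measurement noise, a lower-envelope baseline sits below the mean
  trend by roughly the expected window-extreme of the noise, giving ΔF/F a
  small positive offset; the quiescent-zero property is therefore asserted
  in the noise-free limit.

## Transient detection

The band-removal filter is realized as a zero-phase 4th-order Butterworth
band-stop (the band is prescribed; the family/order is an implementation
choice). Threshold statistics are computed over the analyzed span (default:
full trace; an explicit span argument reproduces per-session cropping).
Onset time is the first sample at which the difference exceeds the
threshold, uncrossed at the previous sample; no interpolation. The
refractory rule keeps the first onset of any cluster. Histogram bins are
half-open `[edge, edge + 0.2)`.

## Event-triggered average and bootstrap

Segments are aligned to the nearest sample; events whose ±(1, 4) s window is
truncated are dropped and counted. The baseline window is `[−1, 0)` —
pre-event samples only — so per-trial baseline means are exactly zero by
construction. The bootstrap redraws |events| timestamps from the continuous
uniform distribution on [min(event), max(event)] per iteration
(timestamps are resampled, not labels), and reports the per-lag mean, SD and
SEM across iterations.

## Spectral analysis

The frequency grid is 3–10 Hz in 0.05 Hz steps; scales follow from the
wavelet's center frequency so results are reproducible across CWT
implementations. Argmax ties break toward the lower frequency. The
cross-condition scaling is a context operation: `apply_global_scaling`
attaches the min/max over the supplied scalogram set, and callers assemble
per-animal sets spanning both food conditions before extracting dominant
frequencies. The amplitude gate compares each timepoint's peak magnitude to
40% of the segment's maximum. The KDE uses an absolute Gaussian bandwidth of
0.2 Hz (a plain kernel-sum, avoiding covariance-factor rescaling
ambiguities); `sd_dom` is the sample SD of the unmasked values.

The mixed model takes the per-segment SD of the dominant-frequency
distribution as the response (condition fixed effect, trial random
intercept). Modelling the pointwise dominant frequency itself would be the
main alternative; the per-segment SD matches how the spread statistic is
defined. Singular random-effects fits fall back to condition-only OLS with
a warning.

The jaw–ΔF/F phase metric is a reconstruction (no formula is prescribed for
it): both signals are band-passed to 3–10 Hz on the photometry grid and the
lag of the peak normalized cross-correlation within chew epochs is searched
over ±0.25 s. Positive lag = jaw leads. Near-periodic signals repeat their
correlation peak every cycle, so near-equal maxima (within 0.5%) resolve to
the smallest |lag|; a peak |correlation| below 0.2 reports the lag as
undefined.

## Kinematics

Savitzky–Golay defaults are an 11-frame window of order 3 at 120 fps (the
filter is prescribed, its parameters are not). More than 20% low-confidence
frames fails the trace. The closure-onset prominence floor is 3× a robust
noise scale of the closing-velocity trace estimated from its first
difference (scaled MAD of diff/√2). A floor based on the raw MAD of the
velocity itself — the more obvious choice — suppresses genuine rhythmic
peaks, because a sinusoid's own MAD (≈0.7 of its amplitude) times 3 exceeds
its peak prominence; the high-frequency noise estimator keeps the floor tied
to jitter, not to the rhythm being detected. Candidate peaks are retained
greedily largest-first under the 40 ms separation. Displacement is reported
as a difference in calibrated units (positive = closed relative to the
maximal open reference, so jaw-closing stimulation gives positive values); a
ratio mode is available since the normalization convention is ambiguous.
The coordinate polarity (`opening_sign`) is configurable because video
geometry varies.

## Tracing

The background threshold is a required argument (its value is
protocol-specific); intensities below it are zeroed, not excluded from the
pixel count. Aggregation averages sections within animal, then animals.
Paired nucleus comparisons default to animal×section observation units, with
per-animal means as an option — the pooling convention is ambiguous and both
are exposed. `simulate_bouton_image` is a synthetic stand-in for a
fluorescence section (punctate Gaussian blobs on noisy background) used to
exercise density contrasts. Input proportions flag (not silently drop)
regions under 0.3% of total input; compartment exclusions remove records
from both counts and totals before any proportion is formed.

## Assumption-gated comparisons

Shapiro–Wilk at α = 0.05 on each sample (or on paired differences), Levene
for independent designs; parametric t tests when the gates pass, Wilcoxon
rank tests otherwise, always two-sided. Constant samples are treated as
non-normal (the gate statistic is undefined); all-zero paired differences
report p = 1 by convention.

## Problem sizes and determinism

Tests and the acceptance script run on 100 s sessions at 120.48 Hz
photometry / 120 fps video (≈12 000 samples per trace), 20 s spectral
segments, 100-iteration bootstraps, and 100-replicate power simulations —
sizes at which every stage completes in seconds while matching the recorded
session scale. All randomness flows from `numpy.random.default_rng` seeded
from explicit integers (the generator derives independent substreams from
`SessionParams.seed`), so identical inputs give byte-identical outputs.

## Known limitations

- The baseline estimator needs quiescent stretches; sessions that are
  events end-to-end yield few valid minima and a degenerate-baseline error.
- The transient detector's mean + 2 SD threshold is not noise-adaptive; on
  noise-dominated traces it produces frequent spurious crossings (see the
  noise-floor note above).
- The LMM Wald p-values are asymptotic; with very few trials the type-I
  rate can drift above nominal.
- Phase estimation assumes a common rhythm; it reports undefined rather
  than a lag when band-limited correlation is weak.
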