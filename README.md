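# oromotor

Quantitative analysis of fiber-photometry and jaw-pose recordings acquired
while head-fixed mice lap, bite and chew — the ingestion behaviors driven by
hindbrain premotor circuits for the jaw musculature. The package takes raw
two-channel photometry (490 nm calcium-dependent signal, 405 nm isosbestic
control), markerless jaw pose tracks at 120 frames/s, and behavioral
annotation tables, and produces transient statistics, bite-triggered
averages, dominant-frequency distributions of the chewing rhythm,
peri-stimulation jaw-displacement metrics and anatomical tracing
quantification. A synthetic-session generator with full ground truth makes
every stage verifiable without animal data.

## What it computes

**Isosbestic correction.** Both channels are boxcar-decimated; a baseline is
defined by rolling-minimum candidates (5 s window) pruned to a minimum
spacing and restricted to low-activity periods; the isosbestic channel is
regressed onto the signal at those samples, giving the fitted baseline
F = offset + scale·iso405 and ΔF/F = (sig490 − F)/F. Bleaching and motion
artifacts are shared between channels and cancel.

**Calcium transients.** After a zero-phase 2–8 Hz band-stop (removing the
chewing rhythm), the delayed difference d[i] = x[i] − x[i−τ] (τ ≈ 100 ms,
the indicator rise time) is thresholded at mean + 2 SD; upward crossings
closer than 0.4 s to a retained onset are discarded. Transient–bite offsets
are histogrammed in 200 ms bins over ±10 s and normalized per bite.

**Bite-triggered average.** ΔF/F segments from −1 to +4 s around each bite,
each baseline-corrected by its own pre-event mean, averaged with SEM; a null
reference redraws bite timestamps uniformly within the observed range
(100 iterations).

**Chewing spectral structure.** 20 s consumption segments are high-passed at
3 Hz and transformed with a complex Morlet CWT (cmor3.0-3.0) on a 3–10 Hz
grid; magnitudes are scaled to the global min/max across both food
conditions; the per-timepoint dominant frequency is gated at 40% of the
segment maximum, summarized by a Gaussian KDE (bandwidth 0.2 Hz), and the
SD of the dominant-frequency distribution is compared between foods with a
linear mixed model (condition fixed effect, trial random intercept).
Chew/bite time fractions are compared with a paired Wilcoxon signed-rank
test, and the jaw–ΔF/F phase is the lag of the peak band-limited
cross-correlation within chew epochs.

**Jaw kinematics.** Pixel positions are calibrated against the 1.25 mm
fiber ferrule, low-confidence frames interpolated, traces Savitzky–Golay
smoothed. Closure onsets are closing-velocity peaks separated by ≥ 40 ms;
peri-stimulation displacement is the mean position 50–500 ms into the laser
pulse relative to the maximal open position 550–50 ms before it, compared
across groups with an assumption-gated (Shapiro–Wilk / Levene) t or rank
test.

**Tracing quantification.** Bouton density per motor-nucleus subdivision as
thresholded mean pixel intensity per ROI with section/animal aggregation and
gated paired tests; retrograde input proportions per region after excluding
off-brain, fiber-tract and ventricular detections.

## Worked example

```python
import numpy as np
from oromotor.synthetic import SessionParams, generate_session
from oromotor.preprocess import preprocess_recording
from oromotor.transients import detect_transients
from oromotor.eta import event_triggered_average, bootstrap_eta
from oromotor.spectral import (compute_scalogram, apply_global_scaling,
                               dominant_frequency_series, frequency_kde_sd)

params = SessionParams(seed=1)          # 100 s almond session, 20 bites
photo, jaw, ann, truth = generate_session(params)
dff, fit, minima = preprocess_recording(photo)
print(f"isosbestic fit: scale={fit.scale:.3f} offset={fit.offset:.4f} r2={fit.r2:.4f}")

events = detect_transients(dff)
hits = sum(np.any(np.abs(events.onset_times - b) <= 0.1) for b in truth.bite_times)
print(f"transients: {len(events.onset_times)} detected, "
      f"{100 * hits / len(truth.bite_times):.0f}% of bites matched within 100 ms")

eta = event_triggered_average(dff, ann.bite_onsets)
null = bootstrap_eta(dff, ann.bite_onsets, n_iter=100, seed=1)
i = int(np.argmax(eta.mean))
print(f"bite ETA: peak dF/F = {eta.mean[i]:.3f} at t = {eta.t_rel[i]:+.2f} s "
      f"(null envelope {null.boot_mean[i] + 3 * null.boot_sd[i]:.3f})")

seg_start = truth.chew_epochs[0][0]
scal = compute_scalogram(dff, (seg_start, seg_start + 20.0))
apply_global_scaling([scal])
dom = dominant_frequency_series(scal)
summary = frequency_kde_sd(dom, condition="almond", trial_id="demo")
print(f"chewing rhythm: dominant frequency {np.median(dom.unmasked):.2f} Hz, "
      f"SD {summary.sd_dom:.2f} Hz")
```

Output:

```
isosbestic fit: scale=1.763 offset=-0.0512 r2=0.9838
transients: 20 detected, 100% of bites matched within 100 ms
bite ETA: peak dF/F = 0.053 at t = +0.39 s (null envelope 0.018)
chewing rhythm: dominant frequency 5.20 Hz, SD 0.14 Hz
```

The fitted scale ≈ 1.76 inverts the generator's isosbestic channel gain;
every bite-locked calcium transient is recovered; the bite-triggered average
peaks near the generated transient amplitude (0.05 ΔF/F) and far above the
resampled-timestamp null; and the chewing band sits at the generated ~5.2 Hz
rhythm. A command-line layer wraps the same stages for file-based work:

```bash
oromotor simulate --seed 1 --out session/
oromotor preprocess --in session/photometry.tsv --out session/dff.tsv
oromotor transients --dff session/dff.tsv --events session/annotations.tsv \
    --out session/transients.tsv --hist-out session/hist.tsv
oromotor eta --dff session/dff.tsv --events session/annotations.tsv \
    --boot 100 --seed 7 --out session/eta.tsv
oromotor kinematics --pose session/jaw.csv --ferrule-px 125 --out session/onsets.tsv
```

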