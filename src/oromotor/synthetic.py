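"""Synthetic ingestion sessions with known ground truth.

Emulates a head-fixed mouse session as recorded by a two-channel fiber
photometry system (490 nm calcium-dependent signal, 405 nm isosbestic
control) together with a markerless jaw pose track and behavioral
annotations.  A session consists of an initial lapping bout followed by an
ingestion phase in which discrete bites alternate with rhythmic chewing
epochs.  The generator produces:

* calcium-indicator transients locked to bite onsets (difference-of-
  exponentials kernel, ~100 ms rise, ~1.5 s decay, GCaMP7s-like);
* a chewing oscillation of the dF/F signal near 5 Hz with peak amplitude
  ~0.02, phase-locked to the jaw closure rhythm;
* exponential photobleaching and a slow multiplicative motion artifact
  shared between the two channels (the isosbestic correction exists to
  remove exactly these);
* a jaw trace with per-cycle closure onsets, large single-cycle excursions
  at bites, and a lick-rate oscillation during the lapping bout;
* closed-loop laser pulse trains triggered a fixed delay after licks.

Every stochastic choice is drawn from ``numpy.random.default_rng`` streams
derived from ``SessionParams.seed``, so a given parameter set reproduces the
same session byte for byte.  The emitted :class:`SessionTruth` carries the
event times and the per-epoch instantaneous chew-frequency profiles, which
downstream recovery tests treat as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ParameterError

__all__ = [
    "SessionParams",
    "SessionTruth",
    "PhotometryRecording",
    "JawTrace",
    "BehaviorAnnotations",
    "FreqProfile",
    "generate_session",
    "generate_photometry",
    "generate_jaw_trace",
    "event_dff_component",
]

# pixel geometry of the simulated profile video (800x800 frame, ferrule
# diameter 1.25 mm spanning ~125 px -> 0.01 mm/px)
REST_PX = 200.0
CHEW_AMP_PX = 100.0
BITE_AMP_PX = 250.0
LICK_AMP_PX = 40.0
BITE_JAW_DUR_S = 0.12
EPOCH_TAPER_S = 0.10

FOOD_TYPES = ("almond", "pasta")


@dataclass(frozen=True)
class SessionParams:
    """Generative parameters of one synthetic session.

    Defaults follow the recorded conditions: photometry decimated to
    120.48 Hz, video at 120 frames/s, chewing near 5.23 Hz with dF/F peaks
    of 0.02, closed-loop stimulation delayed 480 ms after a lick with 1 s
    pulses.  ``food_type`` controls the epoch statistics: pasta sessions
    have more frequent bites, shorter chewing epochs and a broader
    instantaneous chew-frequency jitter than almond sessions.
    """

    duration_s: float = 100.0
    fs_photo: float = 120.48
    fs_video: float = 120.0
    n_bites: int = 20
    chew_freq_hz: float = 5.23
    chew_freq_jitter_hz: float = 0.15
    chew_dff_amp: float = 0.02
    bite_dff_amp: float = 0.05
    lick_dff_amp: float = 0.01
    kernel_rise_s: float = 0.10
    kernel_decay_s: float = 1.5
    bleach_tau_s: float = 600.0
    noise_sd: float = 0.001
    motion_amp: float = 0.01
    jaw_noise_px: float = 0.5
    dropout_rate: float = 0.01
    food_type: str = "almond"
    lick_rate_hz: float = 7.0
    lick_bout_s: float = 4.0
    n_laser_pulses: int = 0
    stim_delay_s: float = 0.480
    stim_dur_s: float = 1.0
    chew_transient_frac: float = 0.0
    baseline_f: float = 1.0
    iso_scale: float = 0.6
    seed: int = 0

    def __post_init__(self):
        for name in ("fs_photo", "fs_video", "lick_rate_hz"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (3.0 <= self.chew_freq_hz <= 10.0):
            raise ParameterError(
                f"chew_freq_hz must lie in [3, 10] Hz, got {self.chew_freq_hz}"
            )
        if self.duration_s < 20.0:
            raise ParameterError(
                f"duration_s must be >= 20 s (minimum spectral segment), got {self.duration_s}"
            )
        if self.fs_video < 2 * self.chew_freq_hz:
            raise ParameterError("fs_video must be at least twice chew_freq_hz")
        if self.n_bites < 0:
            raise ParameterError(f"n_bites must be >= 0, got {self.n_bites}")
        for name in ("kernel_rise_s", "kernel_decay_s", "bleach_tau_s", "stim_dur_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.kernel_decay_s <= self.kernel_rise_s:
            raise ParameterError("kernel_decay_s must exceed kernel_rise_s")
        for name in (
            "noise_sd",
            "motion_amp",
            "jaw_noise_px",
            "chew_dff_amp",
            "bite_dff_amp",
            "lick_dff_amp",
            "chew_freq_jitter_hz",
            "stim_delay_s",
            "dropout_rate",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0.0 <= self.chew_transient_frac <= 1.0):
            raise ParameterError("chew_transient_frac must lie in [0, 1]")
        if self.food_type not in FOOD_TYPES:
            raise ParameterError(
                f"food_type must be one of {FOOD_TYPES}, got {self.food_type!r}"
            )

    @classmethod
    def for_food(cls, food_type: str, **overrides) -> "SessionParams":
        """Parameter set with food-appropriate epoch statistics.

        Pasta is tougher and less brittle than almond: biting is more
        frequent, chewing sequences scarcer and shorter, and the chewing
        rhythm less regular.
        """
        if food_type == "pasta":
            defaults = dict(n_bites=32, chew_freq_jitter_hz=0.45)
        elif food_type == "almond":
            defaults = dict(n_bites=20, chew_freq_jitter_hz=0.15)
        else:
            raise ParameterError(f"food_type must be one of {FOOD_TYPES}, got {food_type!r}")
        defaults.update(overrides)
        return cls(food_type=food_type, **defaults)


class FreqProfile:
    """Piecewise-linear instantaneous frequency over one chewing epoch.

    The phase is the exact integral of the interpolated frequency, so the
    same profile evaluated on the photometry and the video time grids yields
    a single coherent oscillation.
    """

    def __init__(self, t_knots: np.ndarray, f_knots: np.ndarray):
        t_knots = np.asarray(t_knots, dtype=float)
        f_knots = np.asarray(f_knots, dtype=float)
        if t_knots.size < 2 or t_knots.size != f_knots.size:
            raise ParameterError("frequency profile needs >= 2 matched knots")
        self.t_knots = t_knots
        self.f_knots = f_knots
        seg = np.diff(t_knots) * (f_knots[:-1] + f_knots[1:]) / 2.0
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    def freq(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.t_knots, self.f_knots)

    def phase(self, t: np.ndarray) -> np.ndarray:
        """Phase in radians, zero at the first knot; exact piecewise quadratic."""
        t = np.asarray(t, dtype=float)
        i = np.clip(np.searchsorted(self.t_knots, t, side="right") - 1, 0, len(self.t_knots) - 2)
        dt = t - self.t_knots[i]
        slope = (self.f_knots[i + 1] - self.f_knots[i]) / (
            self.t_knots[i + 1] - self.t_knots[i]
        )
        cycles = self._cum[i] + self.f_knots[i] * dt + 0.5 * slope * dt**2
        return 2.0 * np.pi * cycles

    def closure_times(self) -> np.ndarray:
        """Times at which the jaw-closing velocity peaks (phase = 3*pi/2 mod 2*pi)."""
        total = self._cum[-1]  # cycles in the epoch
        targets = 0.75 + np.arange(0, np.floor(total - 0.75) + 1)
        targets = targets[targets <= total]
        # invert the monotone phase with a dense grid
        tt = np.linspace(self.t_knots[0], self.t_knots[-1], max(int(total * 200), 50))
        ph = self.phase(tt) / (2 * np.pi)
        return np.interp(targets, ph, tt)


@dataclass
class SessionTruth:
    """Ground-truth events and generative parameters of a synthetic session."""

    bite_times: np.ndarray
    chew_epochs: list  # (start_s, end_s, food_label)
    lick_times: np.ndarray
    laser_pulses: list  # (onset_s, duration_s)
    transient_times: np.ndarray
    transient_amps: np.ndarray
    closure_onset_times: np.ndarray
    chew_profiles: list  # FreqProfile per chew epoch
    params: SessionParams


@dataclass
class PhotometryRecording:
    """Paired 490 nm / 405 nm traces on a uniform time base."""

    t: np.ndarray
    sig490: np.ndarray
    iso405: np.ndarray
    fs: float

    def __post_init__(self):
        if not (len(self.t) == len(self.sig490) == len(self.iso405)):
            raise ParameterError("t, sig490 and iso405 must have equal lengths")


@dataclass
class JawTrace:
    """Vertical jaw coordinate per video frame.

    ``pos`` is in pixels by default and in millimetres after calibration
    (``units`` says which).  Higher values mean a more open jaw.
    """

    frame: np.ndarray
    pos: np.ndarray
    confidence: np.ndarray
    fs: float
    units: str = "px"

    @property
    def t(self) -> np.ndarray:
        return self.frame / self.fs


@dataclass
class BehaviorAnnotations:
    """Annotated behavioral events of one trial."""

    bite_onsets: np.ndarray
    bite_epochs: list  # (start_s, end_s, food_label)
    chew_epochs: list  # (start_s, end_s, food_label)
    lick_times: np.ndarray
    laser_pulses: list  # (onset_s, duration_s)
    food_type: str = "almond"


def _rng(params: SessionParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def _build_timeline(params: SessionParams) -> SessionTruth:
    rng = _rng(params, 0)
    # lapping bout at the start of the session
    lick_t0 = 1.0
    n_licks = int(np.floor(params.lick_bout_s * params.lick_rate_hz))
    licks = (
        lick_t0
        + np.arange(n_licks) / params.lick_rate_hz
        + rng.normal(0.0, 0.005, n_licks)
    )
    licks = np.sort(licks)

    laser = []
    if params.n_laser_pulses > 0:
        take = np.linspace(0, n_licks - 1, params.n_laser_pulses).round().astype(int)
        for i in take:
            laser.append((float(licks[i] + params.stim_delay_s), params.stim_dur_s))

    # quiet stretches before and after the ingestion phase give the baseline
    # estimator uncontaminated low-activity windows, as in real sessions
    ing_start = lick_t0 + params.lick_bout_s + 5.0
    ing_end = params.duration_s - 8.0
    span = ing_end - ing_start
    bite_gap = 0.3  # bite epoch duration
    post_gap = 0.3  # pause between chew end and the next bite

    bites = np.empty(params.n_bites)
    epochs = []
    profiles = []
    if params.n_bites > 0:
        mean_chew = 2.5 if params.food_type == "almond" else 1.0
        durs = rng.gamma(4.0, mean_chew / 4.0, params.n_bites)
        budget = span - params.n_bites * (bite_gap + post_gap)
        if budget <= 0.5 * params.n_bites:
            raise ParameterError(
                f"n_bites={params.n_bites} does not fit in duration_s={params.duration_s}"
            )
        if durs.sum() > budget:
            durs *= budget / durs.sum()
        durs = np.maximum(durs, 0.5)
        t = ing_start
        for i in range(params.n_bites):
            bites[i] = t
            s, e = t + bite_gap, t + bite_gap + durs[i]
            epochs.append((float(s), float(e), params.food_type))
            t = e + post_gap
        if t > params.duration_s:
            raise ParameterError(
                f"n_bites={params.n_bites} does not fit in duration_s={params.duration_s}"
            )
        for s, e, _ in epochs:
            n_knots = max(int(np.ceil((e - s) / 0.5)) + 1, 2)
            tk = np.linspace(s, e, n_knots)
            fk = np.clip(
                params.chew_freq_hz
                + params.chew_freq_jitter_hz * rng.standard_normal(n_knots),
                3.05,
                9.95,
            )
            profiles.append(FreqProfile(tk, fk))

    closure = (
        np.sort(np.concatenate([p.closure_times() for p in profiles]))
        if profiles
        else np.empty(0)
    )

    # calcium transients: one per bite, plus optionally a subset of chew
    # cycles carrying small kernel events of chew amplitude
    t_times = [bites.copy()]
    t_amps = [np.full(params.n_bites, params.bite_dff_amp)]
    if params.chew_transient_frac > 0 and closure.size:
        pick = rng.random(closure.size) < params.chew_transient_frac
        t_times.append(closure[pick])
        t_amps.append(np.full(int(pick.sum()), params.chew_dff_amp))
    t_all = np.concatenate(t_times)
    a_all = np.concatenate(t_amps)
    order = np.argsort(t_all)

    return SessionTruth(
        bite_times=np.sort(bites),
        chew_epochs=epochs,
        lick_times=licks,
        laser_pulses=laser,
        transient_times=t_all[order],
        transient_amps=a_all[order],
        closure_onset_times=closure,
        chew_profiles=profiles,
        params=params,
    )


def _taper(t: np.ndarray, start: float, end: float, ramp: float) -> np.ndarray:
    """Cosine on/off ramps confining a component to [start, end]."""
    w = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    ramp = min(ramp, (end - start) / 2.0)
    up = np.clip((t - start) / ramp, 0.0, 1.0)
    down = np.clip((end - t) / ramp, 0.0, 1.0)
    w[inside] = (
        0.5 * (1 - np.cos(np.pi * up[inside])) * 0.5 * (1 - np.cos(np.pi * down[inside]))
    )
    # flat top: the product of the two half-ramps is 1 once both saturate
    return w


def _kernel(tau: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient kernel, unit peak, zero for tau < 0."""
    k = np.zeros_like(tau)
    pos = tau >= 0
    k[pos] = np.exp(-tau[pos] / decay) - np.exp(-tau[pos] / rise)
    tpk = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-tpk / decay) - np.exp(-tpk / rise)
    return k / peak


def event_dff_component(
    t: np.ndarray, truth: SessionTruth, params: SessionParams | None = None
) -> np.ndarray:
    """Noiseless dF/F event component on an arbitrary time grid.

    Sum of (i) kernel transients at ``truth.transient_times``, (ii) the
    raised-cosine chewing oscillation within each chew epoch (peaks at
    ``chew_dff_amp``), and (iii) a small tonic elevation during the lapping
    bout.  Exposed separately so tests can compare spectra and amplitudes
    against closed-form expectations.
    """
    if params is None:
        params = truth.params
    t = np.asarray(t, dtype=float)
    e = np.zeros_like(t)
    # bite (and optionally chew-cycle) transients
    for tt, amp in zip(truth.transient_times, truth.transient_amps):
        lo = np.searchsorted(t, tt)
        hi = np.searchsorted(t, tt + params.kernel_rise_s + 8 * params.kernel_decay_s)
        if hi > lo:
            e[lo:hi] += amp * _kernel(
                t[lo:hi] - tt, params.kernel_rise_s, params.kernel_decay_s
            )
    # chewing oscillation, phase shared with the jaw trace
    for (s, ep_end, _), prof in zip(truth.chew_epochs, truth.chew_profiles):
        m = (t >= s) & (t <= ep_end)
        if m.any():
            phase = prof.phase(t[m])
            e[m] += (
                params.chew_dff_amp
                * 0.5
                * (1 - np.cos(phase))
                * _taper(t[m], s, ep_end, EPOCH_TAPER_S)
            )
    # slight tonic recruitment during lapping
    if truth.lick_times.size and params.lick_dff_amp > 0:
        s, ep_end = truth.lick_times[0], truth.lick_times[-1]
        if ep_end > s:
            e += params.lick_dff_amp * _taper(t, s, ep_end, 0.5)
    return e


def _motion(n: int, fs: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Slow multiplicative motion artifact: Gaussian noise low-passed at 0.5 Hz."""
    if amp == 0:
        return np.zeros(n)
    raw = rng.standard_normal(n)
    sos = butter(2, 0.5, btype="lowpass", fs=fs, output="sos")
    m = sosfiltfilt(sos, raw)
    rms = np.sqrt(np.mean(m**2))
    return m / rms * amp if rms > 0 else m


def generate_photometry(
    truth: SessionTruth, params: SessionParams | None = None
) -> PhotometryRecording:
    """Two-channel photometry for a session truth.

    ``sig490 = B(t)*(1 + motion) + B(t)*events + noise`` and
    ``iso405 = iso_scale*B(t)*(1 + motion) + independent noise`` where
    ``B(t) = baseline_f * exp(-t / bleach_tau_s)``.  Bleaching and motion are
    shared between channels; the calcium-event term rides on the bleaching
    baseline (so its dF/F amplitude is stationary) and appears only in the
    490 nm channel.
    """
    if params is None:
        params = truth.params
    rng = _rng(params, 1)
    n = int(round(params.duration_s * params.fs_photo))
    t = np.arange(n) / params.fs_photo
    b = params.baseline_f * np.exp(-t / params.bleach_tau_s)
    m = _motion(n, params.fs_photo, params.motion_amp, rng)
    e = event_dff_component(t, truth, params)
    sig = b * (1 + m) + b * e + params.noise_sd * params.baseline_f * rng.standard_normal(n)
    iso = params.iso_scale * (
        b * (1 + m) + params.noise_sd * params.baseline_f * rng.standard_normal(n)
    )
    return PhotometryRecording(t=t, sig490=sig, iso405=iso, fs=params.fs_photo)


def generate_jaw_trace(
    truth: SessionTruth, params: SessionParams | None = None
) -> JawTrace:
    """Jaw coordinate per frame: chewing rhythm, bite excursions, lick rhythm.

    Increasing coordinate = jaw opening.  The chewing oscillation uses the
    same per-epoch frequency profiles as the photometry component, so the two
    modalities share one phase.
    """
    if params is None:
        params = truth.params
    rng = _rng(params, 2)
    n = int(round(params.duration_s * params.fs_video))
    frame = np.arange(n)
    t = frame / params.fs_video
    pos = np.full(n, REST_PX)

    for (s, ep_end, _), prof in zip(truth.chew_epochs, truth.chew_profiles):
        msk = (t >= s) & (t <= ep_end)
        if msk.any():
            pos[msk] += (
                CHEW_AMP_PX
                * 0.5
                * (1 - np.cos(prof.phase(t[msk])))
                * _taper(t[msk], s, ep_end, EPOCH_TAPER_S)
            )
    for tb in truth.bite_times:
        msk = (t >= tb) & (t <= tb + BITE_JAW_DUR_S)
        if msk.any():
            pos[msk] += BITE_AMP_PX * np.sin(np.pi * (t[msk] - tb) / BITE_JAW_DUR_S) ** 2
    if truth.lick_times.size:
        s, ep_end = truth.lick_times[0], truth.lick_times[-1]
        msk = (t >= s) & (t <= ep_end)
        if msk.any():
            pos[msk] += (
                LICK_AMP_PX
                * 0.5
                * (1 - np.cos(2 * np.pi * params.lick_rate_hz * (t[msk] - s)))
                * _taper(t[msk], s, ep_end, EPOCH_TAPER_S)
            )

    pos = pos + params.jaw_noise_px * rng.standard_normal(n)
    confidence = np.clip(0.97 + 0.02 * rng.standard_normal(n), 0.0, 1.0)
    # occasional tracking dropouts: wild position, low likelihood
    drop = rng.random(n) < params.dropout_rate
    pos[drop] += rng.normal(0.0, 50.0, int(drop.sum()))
    confidence[drop] = rng.uniform(0.05, 0.4, int(drop.sum()))
    return JawTrace(frame=frame, pos=pos, confidence=confidence, fs=params.fs_video)


def generate_session(
    params: SessionParams,
) -> tuple[PhotometryRecording, JawTrace, BehaviorAnnotations, SessionTruth]:
    """Generate one complete synthetic session, deterministic in the seed."""
    truth = _build_timeline(params)
    photo = generate_photometry(truth, params)
    jaw = generate_jaw_trace(truth, params)
    ann = BehaviorAnnotations(
        bite_onsets=truth.bite_times.copy(),
        bite_epochs=[(float(tb), float(tb + 0.3), params.food_type) for tb in truth.bite_times],
        chew_epochs=list(truth.chew_epochs),
        lick_times=truth.lick_times.copy(),
        laser_pulses=list(truth.laser_pulses),
        food_type=params.food_type,
    )
    return photo, jaw, ann, truth
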