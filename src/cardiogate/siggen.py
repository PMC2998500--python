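"""Synthetic physiological sessions with known ground truth.

Generates multi-rate ECG / phonocardiogram / pulse-oximetry / respiration /
microphone traces plus monitoring-unit style trigger tickmarks, with the
statistical structure needed to exercise the downstream fidelity pipeline:
Gaussian R-R intervals, an R-to-first-heart-tone delay of 29.65 +/- 4.43 ms,
a ~350 ms pulse-oximetry peak latency with amplitude/width scatter, a
magneto-hydrodynamic T-wave elevation scaling with static field strength,
gradient-switching noise lines at k/TR and 1/TE, and breath-hold plateaus
in the respiratory trace.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from . import acoustics
from .exceptions import ValidationError
from .physio_io import (FIELD_POSITIONS, ChannelTrace, PhysioLog, SessionMeta,
                        TriggerTrain)

__all__ = [
    "SimulationConfig",
    "CycleSchedule",
    "draw_cycle_schedule",
    "synthesize_ecg",
    "synthesize_pcg",
    "synthesize_pox",
    "synthesize_gradient_noise",
    "synthesize_respiration",
    "simulate_cpmu_triggers",
    "simulate_session",
    "simulate_session_with_truth",
    "default_breath_hold_schedule",
]

# channel sample rates (Hz)
ECG_RATE = 400.0
POX_RATE = 50.0
ACT_RATE = 200.0
RESP_RATE = 50.0
MIC_RATE = 2000.0

# independent substreams derived from the session seed
_STREAM_RR = 0
_STREAM_S1 = 1
_STREAM_MHD = 2
_STREAM_POX = 3
_STREAM_NOISE = 4
_STREAM_RESP = 5


@dataclass
class SimulationConfig:
    """All generator parameters for one synthetic session."""

    n_cycles: int = 60
    rr_mean: float = 900.0          # ms
    rr_sd: float = 50.0             # ms
    r_to_s1_mean: float = 29.65     # ms
    r_to_s1_sd: float = 4.43        # ms
    pox_latency_mean: float = 350.0  # ms
    pox_latency_sd: float = 5.0     # ms
    pox_amp_cv: float = 0.12
    pox_width_cv: float = 0.12
    mhd_gain_at_7T: float = 1.2     # T-wave elevation as multiple of R amplitude
    mhd_amp_cv: float = 0.25        # log-sd of the slow per-cycle elevation drift
    field_position: str = "home"
    tr_s: float = 0.004
    te_s: float = 0.002
    peak_spl_db: float = 120.0      # loudest third-octave gradient-noise band
    snr_cardiac_db: float = 30.0    # cardiac-vs-noise band SNR (10-50 Hz)
    breath_hold_schedule: tuple = None  # ((start_s, duration_s), ...) or None
    seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 0:
            raise ValidationError("n_cycles must be >= 0")
        if not self.rr_mean > 0:
            raise ValidationError("rr_mean must be positive")
        if self.rr_sd < 0 or self.r_to_s1_sd < 0 or self.pox_latency_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not (0 <= self.pox_amp_cv < 1 and 0 <= self.pox_width_cv < 1):
            raise ValidationError("pox cv values must lie in [0, 1)")
        if not self.tr_s > self.te_s > 0:
            raise ValidationError("must have tr_s > te_s > 0")
        if self.field_position not in FIELD_POSITIONS:
            raise ValidationError(f"unknown field_position {self.field_position!r}")
        if self.breath_hold_schedule is not None:
            self.breath_hold_schedule = tuple(
                (float(s), float(d)) for s, d in self.breath_hold_schedule
            )

    @property
    def field_tesla(self) -> float:
        return FIELD_POSITIONS[self.field_position]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CycleSchedule:
    """Ground-truth cardiac timing: R-wave and first-heart-tone instants."""

    r_times: np.ndarray     # s
    s1_times: np.ndarray    # s
    rr: np.ndarray          # per-cycle interval, ms

    def __post_init__(self):
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.s1_times = np.asarray(self.s1_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.r_times.size:
            if np.any(np.diff(self.r_times) <= 0):
                raise ValidationError("r_times must be strictly increasing")
            if np.any(self.s1_times <= self.r_times):
                raise ValidationError("every S1 must follow its R wave")

    @property
    def n(self) -> int:
        return self.r_times.size

    @property
    def duration(self) -> float:
        """Nominal session length: last cycle end plus a short tail."""
        if self.n == 0:
            return 2.0
        return float(self.r_times[-1] + self.rr[-1] / 1000.0 + 0.5)


RR_FLOOR_MS = 300.0   # truncation keeping intervals physiological
S1_DELAY_FLOOR_MS = 1.0


def draw_cycle_schedule(config: SimulationConfig) -> CycleSchedule:
    """Draw R times with Normal(rr_mean, rr_sd) successive differences.

    Intervals are truncated at a 300 ms floor; S1 onsets follow each R by
    an independent Normal(r_to_s1_mean, r_to_s1_sd) delay (1 ms floor).
    """
    n = config.n_cycles
    if n == 0:
        return CycleSchedule(np.empty(0), np.empty(0), np.empty(0))
    rng = config.rng(_STREAM_RR)
    rr = np.maximum(rng.normal(config.rr_mean, config.rr_sd, size=n), RR_FLOOR_MS)
    r_times = np.concatenate([[0.0], np.cumsum(rr[:-1]) / 1000.0])
    delays = np.maximum(
        config.rng(_STREAM_S1).normal(config.r_to_s1_mean, config.r_to_s1_sd, size=n),
        S1_DELAY_FLOOR_MS,
    )
    return CycleSchedule(r_times=r_times, s1_times=r_times + delays / 1000.0, rr=rr)


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

# Five-Gaussian PQRST template: (center offset s, sigma s, amplitude mV).
# The T-wave center scales with the cycle length; all others are fixed
# relative to R.
_ECG_FIXED_BUMPS = (
    (-0.170, 0.025, 0.15),   # P
    (-0.018, 0.008, -0.10),  # Q
    (0.0, 0.007, 1.00),      # R
    (0.018, 0.008, -0.15),   # S
)
_T_FRACTION = 0.33   # T center at R + fraction * RR
_T_SIGMA = 0.050
_T_AMP = 0.30
_MHD_SIGMA = 0.060
_MHD_CENTER_OFFSET = 0.080   # s after the T center; elevations only partially add


_MHD_AR = 0.8   # cycle-to-cycle autocorrelation of the elevation drift


def _mhd_multipliers(config: SimulationConfig, n: int) -> np.ndarray:
    """Mean-one lognormal per-cycle elevation multipliers with slow AR(1)
    drift, mimicking respiratory modulation of the flow-induced voltage."""
    sigma = config.mhd_amp_cv
    if sigma <= 0 or n == 0:
        return np.ones(n)
    eps = config.rng(_STREAM_MHD).standard_normal(n)
    log = np.empty(n)
    log[0] = sigma * eps[0]
    for i in range(1, n):
        log[i] = _MHD_AR * log[i - 1] + np.sqrt(1 - _MHD_AR**2) * sigma * eps[i]
    return np.exp(log - 0.5 * sigma**2)


def _add_bump(y, t, center, sigma, amp):
    lo = np.searchsorted(t, center - 5 * sigma)
    hi = np.searchsorted(t, center + 5 * sigma)
    if hi > lo:
        y[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / sigma) ** 2)


def synthesize_ecg(schedule: CycleSchedule, config: SimulationConfig,
                   duration: float = None, rate: float = ECG_RATE) -> ChannelTrace:
    """Sum-of-Gaussians PQRST trace with an additive MHD T-wave elevation.

    The elevation amplitude is ``mhd_gain_at_7T * R_amplitude * (B/7 T)``
    on average, with per-cycle lognormal scatter of ``mhd_amp_cv`` so that
    threshold-based R detection degrades progressively with field strength.
    """
    if duration is None:
        duration = schedule.duration
    t = np.arange(int(round(duration * rate))) / rate
    y = np.zeros_like(t)
    if schedule.n:
        mhd_scale = config.mhd_gain_at_7T * (config.field_tesla / 7.0)
        mults = _mhd_multipliers(config, schedule.n)
        for i, r in enumerate(schedule.r_times):
            rr_s = schedule.rr[i] / 1000.0
            for off, sig, amp in _ECG_FIXED_BUMPS:
                _add_bump(y, t, r + off, sig, amp)
            t_center = r + _T_FRACTION * rr_s
            _add_bump(y, t, t_center, _T_SIGMA, _T_AMP)
            if mhd_scale > 0:
                _add_bump(y, t, t_center + _MHD_CENTER_OFFSET, _MHD_SIGMA,
                          mhd_scale * mults[i])
    return ChannelTrace(label="ECG", rate=rate, samples=y, units="mV")


# ---------------------------------------------------------------------------
# phonocardiogram
# ---------------------------------------------------------------------------

S1_DURATION = 0.080   # s
S1_FREQ = 35.0        # Hz
S2_DURATION = 0.050
S2_FREQ = 50.0
S2_REL_AMP = 0.40
S2_PHASE_FRACTION = 0.35   # S2 onset at R + fraction * RR


def _add_tone_burst(y, t, onset, duration, freq, amp):
    lo = np.searchsorted(t, onset)
    hi = np.searchsorted(t, onset + duration)
    if hi > lo:
        tau = t[lo:hi] - onset
        y[lo:hi] += amp * np.sin(np.pi * tau / duration) ** 2 * np.sin(2 * np.pi * freq * tau)


def synthesize_pcg(schedule: CycleSchedule, config: SimulationConfig,
                   duration: float = None, rate: float = ACT_RATE,
                   amplitude: float = 1.0) -> ChannelTrace:
    """Phonocardiogram: an S1 burst at each first-heart-tone onset plus a
    smaller S2 burst in early diastole.

    Bursts are sine-squared-enveloped oscillations; the S1 envelope peaks
    half its duration after the onset, and >95 % of S1 spectral energy lies
    below 100 Hz.
    """
    if duration is None:
        duration = schedule.duration
    t = np.arange(int(round(duration * rate))) / rate
    y = np.zeros_like(t)
    for i in range(schedule.n):
        _add_tone_burst(y, t, schedule.s1_times[i], S1_DURATION, S1_FREQ, amplitude)
        s2_onset = schedule.r_times[i] + S2_PHASE_FRACTION * schedule.rr[i] / 1000.0
        _add_tone_burst(y, t, s2_onset, S2_DURATION, S2_FREQ, amplitude * S2_REL_AMP)
    return ChannelTrace(label="ACT" if rate <= 400 else "MIC", rate=rate,
                        samples=y, units="au" if rate <= 400 else "Pa")


# ---------------------------------------------------------------------------
# pulse oximetry
# ---------------------------------------------------------------------------

POX_PEAK_TAU = 0.060      # s; systolic peak width (fast rise)
POX_SHOULDER_DELAY = 0.18  # s; broad plateau/decay shoulder after the peak
POX_SHOULDER_TAU = 0.28
POX_SHOULDER_AMP = 0.75


def _pox_pulse(tau, width):
    """Unit pulse: narrow systolic peak riding on a broad trailing shoulder
    (fast rise, flat-ish top, slow decay).  ``width`` scales time."""
    u = tau / width
    return (np.exp(-np.square(u / POX_PEAK_TAU))
            + POX_SHOULDER_AMP * np.exp(-np.square((u - POX_SHOULDER_DELAY)
                                                   / POX_SHOULDER_TAU)))


def _pox_peak_shift_unit() -> float:
    """Offset of the unit pulse's true maximum from tau = 0 (numeric)."""
    tau = np.linspace(-0.05, 0.08, 20001)
    return float(tau[np.argmax(_pox_pulse(tau, 1.0))])


def synthesize_pox(schedule: CycleSchedule, config: SimulationConfig,
                   duration: float = None, rate: float = POX_RATE) -> ChannelTrace:
    """Pulse-oximetry trace: one asymmetric pulse per cycle.

    Each pulse peaks ``Normal(pox_latency_mean, pox_latency_sd)`` ms after
    its R wave, with per-pulse amplitude and width multipliers drawn
    ``Normal(1, cv)``.  The shape rises fast and decays slowly over a flat
    plateau, so threshold-crossing trigger jitter emerges from the
    amplitude/width scatter.
    """
    if duration is None:
        duration = schedule.duration
    t = np.arange(int(round(duration * rate))) / rate
    y = np.zeros_like(t)
    if schedule.n:
        rng = config.rng(_STREAM_POX)
        lat = rng.normal(config.pox_latency_mean, config.pox_latency_sd, size=schedule.n)
        amps = np.maximum(rng.normal(1.0, config.pox_amp_cv, size=schedule.n), 0.1)
        widths = np.maximum(rng.normal(1.0, config.pox_width_cv, size=schedule.n), 0.3)
        lat = np.maximum(lat, 50.0)  # pulse never precedes its R wave
        peaks = schedule.r_times + lat / 1000.0
        for p, a, w in zip(peaks, amps, widths):
            lo = np.searchsorted(t, p - 0.45 * w)
            hi = np.searchsorted(t, p + 1.1 * w)
            if hi > lo:
                y[lo:hi] += a * _pox_pulse(t[lo:hi] - p, w)
    return ChannelTrace(label="POX", rate=rate, samples=y, units="au")


def pox_peak_times(schedule: CycleSchedule, config: SimulationConfig) -> np.ndarray:
    """Ground-truth pulse peak instants (same draws as :func:`synthesize_pox`).

    Accounts for the small width-dependent shift of the waveform maximum
    caused by the trailing shoulder.
    """
    if schedule.n == 0:
        return np.empty(0)
    rng = config.rng(_STREAM_POX)
    lat = rng.normal(config.pox_latency_mean, config.pox_latency_sd, size=schedule.n)
    rng.normal(1.0, config.pox_amp_cv, size=schedule.n)  # keep stream aligned
    widths = np.maximum(rng.normal(1.0, config.pox_width_cv, size=schedule.n), 0.3)
    lat = np.maximum(lat, 50.0)
    return schedule.r_times + lat / 1000.0 + _pox_peak_shift_unit() * widths


# ---------------------------------------------------------------------------
# gradient noise
# ---------------------------------------------------------------------------

# relative line amplitudes for the k/TR harmonics and the 1/TE line
_LINE_REL_AMPS = ((1, "tr", 1.0), (2, "tr", 0.7), (3, "tr", 0.5), (1, "te", 0.8))
_THIRD_OCTAVE = 2.0 ** (1.0 / 6.0)
_FLOOR_DB_BELOW_PEAK = 50.0


def gradient_line_frequencies(config: SimulationConfig) -> dict:
    """Unique line frequencies (Hz) -> coherent relative amplitude."""
    lines: dict = {}
    for k, which, amp in _LINE_REL_AMPS:
        f = k / (config.tr_s if which == "tr" else config.te_s)
        lines[f] = lines.get(f, 0.0) + amp
    return lines


def synthesize_gradient_noise(config: SimulationConfig, duration: float,
                              rate: float = MIC_RATE) -> ChannelTrace:
    """Gradient-switching acoustic noise: sharp lines at k/TR (k=1..3) and
    1/TE over a broadband floor 50 dB below the loudest line band.

    The output is calibrated in pascal so that the loudest third-octave
    band reads ``peak_spl_db`` dB SPL.
    """
    if duration < 0:
        raise ValidationError("duration must be >= 0")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    lines = gradient_line_frequencies(config)
    y = np.zeros(n)
    for f, amp in lines.items():
        if f < rate / 2:
            y += amp * np.sin(2 * np.pi * f * t)
    # loudest third-octave band power from the line inventory
    peak_band_power = 0.0
    for f in lines:
        lo, hi = f / _THIRD_OCTAVE, f * _THIRD_OCTAVE
        p = sum(0.5 * a**2 for g, a in lines.items() if lo <= g <= hi and g < rate / 2)
        peak_band_power = max(peak_band_power, p)
    if n and peak_band_power > 0:
        bw = max(f * (_THIRD_OCTAVE - 1 / _THIRD_OCTAVE) for f in lines)
        floor_power = peak_band_power * 10 ** (-_FLOOR_DB_BELOW_PEAK / 10.0)
        sigma = np.sqrt(floor_power * (rate / 2) / bw)
        y += sigma * config.rng(_STREAM_NOISE).standard_normal(n)
        scale = acoustics.P_REF * 10 ** (config.peak_spl_db / 20.0) / np.sqrt(peak_band_power)
        y *= scale
    return ChannelTrace(label="MIC", rate=rate, samples=y, units="Pa")


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------

RESP_FREQ = 0.22          # Hz free breathing
RESP_HOLD_RESIDUAL = 0.02  # residual amplitude fraction during a hold
_RESP_RAMP = 0.3          # s transition into/out of a hold


def _validate_holds(holds, duration):
    holds = sorted((float(s), float(s) + float(d)) for s, d in holds)
    for (s1, e1), (s2, e2) in zip(holds, holds[1:]):
        if s2 < e1:
            raise ValidationError("breath-hold intervals overlap")
    for s, e in holds:
        if s < 0 or e > duration + 1e-9:
            raise ValidationError("breath-hold interval outside [0, duration]")
    return holds


def _breathing(t_local: np.ndarray) -> np.ndarray:
    return (np.sin(2 * np.pi * RESP_FREQ * t_local)
            + 0.2 * np.sin(4 * np.pi * RESP_FREQ * t_local + 0.9))


def synthesize_respiration(config: SimulationConfig, duration: float,
                           rate: float = RESP_RATE) -> ChannelTrace:
    """Quasi-periodic free breathing with near-constant end-expiratory
    plateaus during each scheduled breath hold.

    Residual plateau amplitude is 2 % of the breathing depth.  Breathing
    blends into each hold over a short ramp and resumes with a fresh
    inhale (phase reset) at the hold's end, giving sharp hold boundaries.
    """
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    holds = _validate_holds(config.breath_hold_schedule or (), duration)
    y = np.empty(n)
    prev_end = 0.0
    for s, e in list(holds) + [(duration, duration)]:
        free = (t >= prev_end) & (t < s)
        y[free] = _breathing(t[free] - prev_end)
        hold = (t >= s) & (t < e)
        th = t[hold] - s
        carried = _breathing(th + (s - prev_end))
        residual = RESP_HOLD_RESIDUAL * np.sin(2 * np.pi * RESP_FREQ * th)
        w = 0.5 * (1 + np.cos(np.pi * np.clip(th / _RESP_RAMP, 0.0, 1.0)))
        y[hold] = w * carried + (1 - w) * residual
        prev_end = e
    return ChannelTrace(label="RESP", rate=rate, samples=y, units="au")


def default_breath_hold_schedule(duration: float, hold_s: float = 18.0,
                                 gap_s: float = 5.0, start_s: float = 2.0):
    """Repeated breath-held acquisition windows covering the session."""
    holds = []
    start = start_s
    while start + hold_s <= duration - 0.5:
        holds.append((start, hold_s))
        start += hold_s + gap_s
    return tuple(holds)


# ---------------------------------------------------------------------------
# monitoring-unit trigger emulation
# ---------------------------------------------------------------------------

def _threshold_triggers(trace: ChannelTrace, threshold_fraction: float = 0.6,
                        peak_window_s: float = 3.0,
                        refractory_ms: float = 300.0) -> np.ndarray:
    """Rising-edge threshold detector on a raw waveform (sample resolution)."""
    x = trace.samples
    if x.size == 0:
        return np.empty(0)
    peak = acoustics.running_peak(x, trace.rate, peak_window_s)
    thr = threshold_fraction * np.maximum(peak, 1e-12)
    above = x > thr
    crossings = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    refractory = refractory_ms * 1e-3
    times = []
    for i in crossings:
        t = trace.t0 + i / trace.rate
        if not times or t - times[-1] >= refractory:
            times.append(t)
    return np.asarray(times)


def simulate_cpmu_triggers(log_or_channels, modality: str,
                           config: SimulationConfig) -> TriggerTrain:
    """Emulate the scanner monitoring unit's trigger tickmark generation.

    ECG and POX use a rising-edge detector (threshold 60 % of the trailing
    3 s peak, 300 ms refractory) on the raw waveform; ACT goes through the
    heart-sound filter/envelope chain of
    :func:`cardiogate.acoustics.detect_s1_triggers`.  At the isocenter the
    ECG detector fires on large MHD elevations, producing the
    mis-registrations the fidelity pipeline quantifies.
    """
    channels = getattr(log_or_channels, "channels", log_or_channels)
    if modality not in ("ECG", "POX", "ACT"):
        raise ValidationError(f"unknown trigger modality {modality!r}")
    if modality not in channels:
        raise ValidationError(f"channel {modality!r} not present")
    trace = channels[modality]
    if modality == "ACT":
        spec = None
        if 105.0 < trace.rate / 2:
            spec = acoustics.design_heart_sound_filter(trace.rate)
        train = acoustics.detect_s1_triggers(trace, spec)
        return TriggerTrain(modality="ACT", times=train.times)
    times = _threshold_triggers(trace)
    return TriggerTrain(modality=modality, times=times)


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def _band_power_in_windows(x, rate, windows, f_lo, f_hi):
    """Mean per-window band power (Hann periodogram; the taper keeps the
    strong gradient lines from leaking into low-frequency bands)."""
    from scipy.signal import periodogram
    powers = []
    for s, e in windows:
        lo, hi = int(round(s * rate)), int(round(e * rate))
        seg = x[lo:hi]
        if seg.size < 8:
            continue
        freqs, psd = periodogram(seg, fs=rate, window="hann", detrend=False)
        df = freqs[1] - freqs[0]
        mask = (freqs >= f_lo) & (freqs <= f_hi)
        powers.append(float(psd[mask].sum() * df))
    if not powers:
        raise ValidationError("no usable analysis windows")
    return float(np.mean(powers))


CARDIAC_WINDOW = 0.12   # s, centered on each S1 burst
CARDIAC_WINDOW_LEAD = 0.02   # s before the S1 onset (centers the burst)
SNR_BAND = (10.0, 50.0)


def _truth_windows(schedule: CycleSchedule, holds):
    """Heart-sound and noise-only analysis windows inside breath holds."""
    def inside(s, e):
        return any(s >= hs and e <= hs + hd for hs, hd in holds)

    cardiac, noise = [], []
    for i in range(schedule.n):
        s1 = schedule.s1_times[i]
        rr_s = schedule.rr[i] / 1000.0
        cw = (s1 - CARDIAC_WINDOW_LEAD, s1 - CARDIAC_WINDOW_LEAD + CARDIAC_WINDOW)
        nw = (schedule.r_times[i] + 0.55 * rr_s, schedule.r_times[i] + 0.85 * rr_s)
        if inside(*cw):
            cardiac.append(cw)
        if inside(*nw):
            noise.append(nw)
    return cardiac, noise


def simulate_session_with_truth(config: SimulationConfig):
    """Build a full synthetic :class:`PhysioLog` plus its ground truth.

    The microphone channel mixes the phonocardiogram with gradient noise
    scaled so that the 10-50 Hz band SNR between heart-sound and noise-only
    windows equals ``config.snr_cardiac_db``.  Returns ``(log, truth)``
    where ``truth`` records R/S1/POX-peak instants, breath holds and the
    acoustic analysis windows.
    """
    schedule = draw_cycle_schedule(config)
    duration = schedule.duration
    holds = config.breath_hold_schedule
    if holds is None:
        holds = default_breath_hold_schedule(duration)
    cfg = config if config.breath_hold_schedule == holds else _with_holds(config, holds)

    ecg = synthesize_ecg(schedule, cfg, duration)
    act = synthesize_pcg(schedule, cfg, duration, rate=ACT_RATE)
    pox = synthesize_pox(schedule, cfg, duration)
    resp = synthesize_respiration(cfg, duration)

    noise = synthesize_gradient_noise(cfg, duration, rate=MIC_RATE)
    heart = synthesize_pcg(schedule, cfg, duration, rate=MIC_RATE)
    cardiac_w, noise_w = _truth_windows(schedule, holds)
    mic_samples = noise.samples.copy()
    if cardiac_w and noise_w and heart.samples.any():
        p_noise = _band_power_in_windows(noise.samples, MIC_RATE, noise_w, *SNR_BAND)
        p_heart = _band_power_in_windows(heart.samples, MIC_RATE, cardiac_w, *SNR_BAND)
        k = np.sqrt(p_noise / p_heart) * 10 ** (cfg.snr_cardiac_db / 20.0)
        mic_samples = mic_samples + k * heart.samples
    mic = ChannelTrace(label="MIC", rate=MIC_RATE, samples=mic_samples, units="Pa")

    channels = {"ECG": ecg, "POX": pox, "ACT": act, "RESP": resp, "MIC": mic}
    triggers = {
        mod: simulate_cpmu_triggers(channels, mod, cfg) for mod in ("ECG", "POX", "ACT")
    }
    log = PhysioLog(
        channels=channels,
        triggers=triggers,
        meta=SessionMeta(field_position=cfg.field_position, tr_s=cfg.tr_s,
                         te_s=cfg.te_s, subject=f"sim{cfg.seed}"),
    )
    truth = {
        "r_times": schedule.r_times.tolist(),
        "s1_times": schedule.s1_times.tolist(),
        "rr_ms": schedule.rr.tolist(),
        "pox_peak_times": pox_peak_times(schedule, cfg).tolist(),
        "breath_holds": [list(h) for h in holds],
        "cardiac_windows": [list(w) for w in cardiac_w],
        "noise_windows": [list(w) for w in noise_w],
    }
    return log, truth


def _with_holds(config: SimulationConfig, holds) -> SimulationConfig:
    return replace(config, breath_hold_schedule=tuple(holds))


def simulate_session(config: SimulationConfig) -> PhysioLog:
    """Full synthetic session (see :func:`simulate_session_with_truth`)."""
    log, _ = simulate_session_with_truth(config)
    return log
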