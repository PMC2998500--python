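"""Waveform post-processing and trigger-fidelity statistics.

Implements the five-step analysis applied to logged sessions: breath-hold
gating of the traces, cross-correlation segmentation of the ECG into R-R
intervals with temporal realignment, application of the segmentation mask
to the simultaneously recorded channels, reassignment of trigger tickmarks
to the realigned cycles, and per-modality interval/offset statistics
(mean, SD, peak-to-peak jitter, failure rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateSignalError, InsufficientDataError, ValidationError
from .physio_io import ChannelTrace, PhysioLog, TriggerTrain

__all__ = [
    "BreathHoldInterval",
    "CycleSegmentation",
    "CycleOffsets",
    "TriggerStats",
    "identify_breath_holds",
    "segment_rr",
    "apply_segmentation_mask",
    "reassign_tickmarks",
    "trigger_jitter",
    "cycle_statistics",
    "trigger_offset_stats",
    "failure_rate",
    "flag_sd_ratio",
    "analyze_session",
    "load_table1",
]

OVERLAY_RATE = 400.0   # common timebase for per-cycle excerpts (highest logged rate)


@dataclass(frozen=True)
class BreathHoldInterval:
    start: float
    end: float

    def __post_init__(self):
        if not self.end > self.start:
            raise ValidationError("breath hold must satisfy end > start")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


# ---------------------------------------------------------------------------
# breath-hold gating
# ---------------------------------------------------------------------------

def identify_breath_holds(resp: ChannelTrace, min_duration_s: float = 5.0,
                          quiet_fraction: float = 0.1,
                          window_s: float = 2.0) -> list:
    """Find maximal quiet intervals of the respiratory trace.

    An interval qualifies when the centered rolling SD (``window_s``) stays
    below ``quiet_fraction`` times the whole-trace SD for at least
    ``min_duration_s``.
    """
    if resp.label != "RESP":
        raise ValidationError(f"expected the RESP channel, got {resp.label!r}")
    w = int(round(window_s * resp.rate))
    if resp.n < w:
        raise ValidationError("trace shorter than the rolling window")
    rolling_sd = (
        pd.Series(resp.samples).rolling(w, center=True, min_periods=max(w // 2, 2))
        .std().to_numpy()
    )
    total_sd = float(np.std(resp.samples))
    quiet = rolling_sd < quiet_fraction * total_sd
    holds = []
    edges = np.flatnonzero(np.diff(np.r_[False, quiet, False]))
    half = window_s / 2.0  # a quiet rolling window implies quiet w/2 beyond it
    for lo, hi in zip(edges[::2], edges[1::2]):
        start = max(resp.t0 + lo / resp.rate - half, resp.t0)
        end = min(resp.t0 + (hi - 1) / resp.rate + half, resp.end)
        if end - start >= min_duration_s:
            holds.append(BreathHoldInterval(start, end))
    return holds


# ---------------------------------------------------------------------------
# R-R segmentation by cross correlation
# ---------------------------------------------------------------------------

@dataclass
class CycleSegmentation:
    """R-R cycle boundaries with per-cycle realignment shifts (ms).

    ``cycles[i]`` is the (start, end) of detected cycle ``i`` on the
    session clock; ``shifts[i]`` is the offset (ms) that maximizes the
    normalized cross correlation of that cycle with the reference interval.
    """

    reference: tuple
    cycles: list
    shifts: np.ndarray
    rate: float

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=float)
        starts = [c[0] for c in self.cycles]
        if any(e <= s for s, e in self.cycles):
            raise ValidationError("cycles must have positive length")
        if any(s2 < e1 - 1e-9 for (_, e1), (s2, _) in zip(self.cycles, self.cycles[1:])):
            raise ValidationError("cycles must be ordered and non-overlapping")
        if tuple(self.reference) not in {tuple(c) for c in self.cycles}:
            raise ValidationError("reference must be one of the cycles")

    @property
    def n(self) -> int:
        return len(self.cycles)

    @property
    def r_times(self) -> np.ndarray:
        return np.asarray([c[0] for c in self.cycles])


def _ricker(sigma_samples: float) -> np.ndarray:
    """Second-derivative-of-Gaussian kernel; narrow-peak matched filter that
    suppresses the broad MHD elevation."""
    half = int(np.ceil(4 * sigma_samples))
    x = np.arange(-half, half + 1, dtype=float)
    k = (1 - (x / sigma_samples) ** 2) * np.exp(-0.5 * (x / sigma_samples) ** 2)
    return k / np.sqrt(np.sum(k**2))

R_KERNEL_SIGMA_S = 0.007     # matches the R-wave width
R_REFRACTORY_S = 0.300
R_THRESHOLD_FRACTION = 0.5


def detect_r_peaks(ecg: ChannelTrace) -> np.ndarray:
    """Template-matched R-wave instants (sub-sample, parabolic refinement).

    Works at any field position: the narrow matched kernel responds weakly
    to the wide T-wave/MHD elevation, emulating detection on the clean
    home-position waveform.
    """
    x = ecg.samples
    if x.size == 0 or np.ptp(x) == 0:
        raise DegenerateSignalError("ECG trace is constant; cannot locate R waves")
    kernel = _ricker(R_KERNEL_SIGMA_S * ecg.rate)
    m = np.convolve(x, kernel[::-1], mode="same")
    thr = R_THRESHOLD_FRACTION * np.max(m)
    refr = int(round(R_REFRACTORY_S * ecg.rate))
    above = m > thr
    idx = []
    i = 0
    n = m.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            pk = i + int(np.argmax(m[i:j + 1]))
            idx.append(pk)
            i = pk + refr
        else:
            i += 1
    # drop peaks lacking full kernel support at the trace edges (truncated
    # first/last beats would otherwise bias the reference alignment)
    guard = (kernel.size - 1) // 2
    idx = [pk for pk in idx if guard <= pk <= n - 1 - guard]
    peaks = []
    for pk in idx:
        if 0 < pk < n - 1:
            denom = m[pk - 1] - 2 * m[pk] + m[pk + 1]
            delta = 0.5 * (m[pk - 1] - m[pk + 1]) / denom if denom != 0 else 0.0
            peaks.append(pk + float(np.clip(delta, -1, 1)))
        else:
            peaks.append(float(pk))
    return ecg.t0 + np.asarray(peaks) / ecg.rate


MAX_SHIFT_S = 0.100   # admissible realignment search range
CORR_WINDOW_S = 0.200  # leading portion of the cycle used for correlation:
                       # QRS-dominated, before the (cycle-length dependent)
                       # T wave, so realignment locks onto the R complex


def _norm_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    return float(np.sum(a * b) / denom) if denom > 0 else -np.inf


def segment_rr(ecg: ChannelTrace, holds) -> CycleSegmentation:
    """Segment the ECG into R-R intervals and realign them to a reference.

    The reference is the first complete R-R interval inside the first
    breath hold; every other cycle gets the integer-sample shift (within
    +/-100 ms) that maximizes its normalized cross correlation with the
    reference.
    """
    if np.ptp(ecg.samples) == 0:
        raise DegenerateSignalError("constant ECG yields degenerate correlations")
    r_times = detect_r_peaks(ecg)
    holds = list(holds)
    if holds:
        keep = []
        for i in range(r_times.size - 1):
            if any(h.contains(r_times[i]) and h.contains(r_times[i + 1]) for h in holds):
                keep.append(i)
    else:
        keep = list(range(max(r_times.size - 1, 0)))
    if len(keep) < 2:
        raise InsufficientDataError("need at least two cardiac cycles inside holds")

    cycles = [(float(r_times[i]), float(r_times[i + 1])) for i in keep]
    ref = cycles[0]
    x = ecg.samples
    rate = ecg.rate
    ref_i0 = int(round((ref[0] - ecg.t0) * rate))
    ref_len = min(int(round((ref[1] - ref[0]) * rate)),
                  int(round(CORR_WINDOW_S * rate)))
    ref_seg = x[ref_i0:ref_i0 + ref_len]
    max_shift = int(round(MAX_SHIFT_S * rate))
    # sub-sample residual of snapping a window start onto the sample grid
    ref_snap = ref_i0 / rate + ecg.t0 - ref[0]

    shifts = np.zeros(len(cycles))
    for ci, (start, _) in enumerate(cycles):
        if (start, cycles[ci][1]) == ref:
            continue
        i0 = int(round((start - ecg.t0) * rate))
        best, best_shift = -np.inf, 0
        for sh in range(-max_shift, max_shift + 1):
            lo = i0 + sh
            if lo < 0 or lo + ref_len > x.size:
                continue
            c = _norm_corr(ref_seg, x[lo:lo + ref_len])
            if c > best:
                best, best_shift = c, sh
        # `best_shift` moves this window onto the reference content, i.e.
        # the cycle content itself sits displaced by the opposite amount;
        # the known grid-snapping residuals are removed so that window
        # extraction rounding does not leak into the statistics.  The
        # reported shift is the content displacement: trigger offsets add
        # it, excerpt windows subtract it.
        snap = i0 / rate + ecg.t0 - start
        shifts[ci] = -(best_shift / rate + snap - ref_snap) * 1000.0
    return CycleSegmentation(reference=ref, cycles=cycles, shifts=shifts, rate=rate)


def apply_segmentation_mask(seg: CycleSegmentation, other: ChannelTrace):
    """Cut each (realigned) cycle window out of another channel.

    Every excerpt covers the reference-interval length starting at the
    cycle's shifted start, resampled by linear interpolation onto a common
    400 samples/s timebase.  Returns ``(tau, excerpts)`` where ``tau`` is
    the within-cycle time axis.
    """
    ref_len = seg.reference[1] - seg.reference[0]
    span = (other.t0, other.end)
    # the shift is the cycle content's displacement, so the window that
    # tracks the realigned content starts earlier by that amount
    starts = [c[0] - s / 1000.0 for c, s in zip(seg.cycles, seg.shifts)]
    if all(st + ref_len < span[0] or st > span[1] for st in starts):
        raise ValidationError("channel does not overlap the segmentation span")
    tau = np.arange(int(round(ref_len * OVERLAY_RATE))) / OVERLAY_RATE
    t_other = other.times()
    excerpts = [np.interp(st + tau, t_other, other.samples) for st in starts]
    return tau, excerpts


# ---------------------------------------------------------------------------
# tickmark reassignment and statistics
# ---------------------------------------------------------------------------

@dataclass
class CycleOffsets:
    """Per-cycle trigger offsets (ms, trigger minus cycle R, shift applied).

    ``offsets[i]`` is NaN for cycles without any tickmark; ``n_extra``
    counts tickmarks beyond the first within a cycle (excluded from the
    statistics, diagnostic only).
    """

    offsets: np.ndarray
    n_extra: int = 0

    @property
    def finite(self) -> np.ndarray:
        return self.offsets[np.isfinite(self.offsets)]

    @property
    def n_missed(self) -> int:
        return int(np.sum(~np.isfinite(self.offsets)))


#: Detector thresholds fire on the rising flank, slightly before the R peak;
#: cycle containment is shifted early by this guard so such ticks stay with
#: their own cycle.
CYCLE_GUARD_S = 0.050


def reassign_tickmarks(seg: CycleSegmentation, triggers: TriggerTrain,
                       r_times=None) -> CycleOffsets:
    """Assign each tickmark to the cycle containing it.

    The offset is ``tickmark - cycle R + cycle shift`` in ms; the earliest
    tickmark wins when a cycle holds several.  Cycles without tickmarks are
    reported as missed (NaN).  Containment windows start 50 ms before each
    cycle so rising-flank triggers just ahead of the R peak are kept.
    """
    if r_times is None:
        r_times = seg.r_times
    r_times = np.asarray(r_times, dtype=float)
    offsets = np.full(seg.n, np.nan)
    extra = 0
    times = triggers.times
    for i, (start, end) in enumerate(seg.cycles):
        in_cycle = times[(times >= start - CYCLE_GUARD_S) & (times < end - CYCLE_GUARD_S)]
        if in_cycle.size == 0:
            continue
        extra += in_cycle.size - 1
        offsets[i] = (in_cycle[0] - r_times[i]) * 1000.0 + seg.shifts[i]
    return CycleOffsets(offsets=offsets, n_extra=extra)


def trigger_jitter(offsets) -> float:
    """Peak-to-peak spread (max - min) of per-cycle offsets, ms."""
    vals = _finite_offsets(offsets)
    if vals.size < 2:
        raise InsufficientDataError("jitter needs at least two offsets")
    return float(np.max(vals) - np.min(vals))


def cycle_statistics(triggers: TriggerTrain):
    """Sample mean and SD (n-1) of successive trigger intervals, ms."""
    if triggers.n < 3:
        raise InsufficientDataError("need at least three triggers (two intervals)")
    iv = np.diff(triggers.times) * 1000.0
    return float(np.mean(iv)), float(np.std(iv, ddof=1))


def trigger_offset_stats(offsets):
    """Sample mean and SD (n-1) of per-cycle trigger offsets, ms."""
    vals = _finite_offsets(offsets)
    if vals.size < 2:
        raise InsufficientDataError("offset statistics need at least two offsets")
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


FAILURE_BIN_MS = 20.0


def failure_rate(offsets, tolerance_ms: float = 100.0) -> float:
    """Fraction of cycles whose trigger lands away from the modal offset.

    The modal offset is the center of the tallest 20 ms histogram bin; an
    offset farther than ``tolerance_ms`` from it counts as a
    mis-registration, and missed cycles count as failures too.
    """
    if isinstance(offsets, CycleOffsets):
        vals, n_missed = offsets.finite, offsets.n_missed
    else:
        arr = np.asarray(offsets, dtype=float)
        vals, n_missed = arr[np.isfinite(arr)], int(np.sum(~np.isfinite(arr)))
    total = vals.size + n_missed
    if total == 0:
        raise InsufficientDataError("failure rate needs at least one cycle")
    if vals.size == 0:
        return 1.0
    lo = np.floor(vals.min() / FAILURE_BIN_MS) * FAILURE_BIN_MS
    hi = np.ceil(vals.max() / FAILURE_BIN_MS) * FAILURE_BIN_MS + FAILURE_BIN_MS
    edges = np.arange(lo, hi + FAILURE_BIN_MS / 2, FAILURE_BIN_MS)
    counts, edges = np.histogram(vals, bins=edges)
    mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    failures = int(np.sum(np.abs(vals - mode) > tolerance_ms)) + n_missed
    return failures / total


def _finite_offsets(offsets) -> np.ndarray:
    if isinstance(offsets, CycleOffsets):
        return offsets.finite
    arr = np.asarray(offsets, dtype=float)
    return arr[np.isfinite(arr)]


def flag_sd_ratio(sd_ecg, sd_act, ratio: float, strict: bool = False) -> int:
    """Count subjects whose ECG-derived SD is at least ``ratio`` times the
    ACT-derived SD (non-strict comparison by default)."""
    if not ratio >= 0:
        raise ValidationError("ratio must be non-negative")
    sd_ecg = np.asarray(sd_ecg, dtype=float)
    sd_act = np.asarray(sd_act, dtype=float)
    if sd_ecg.size == 0 or sd_ecg.shape != sd_act.shape:
        raise ValidationError("need matching, nonempty SD vectors")
    if strict:
        return int(np.sum(sd_ecg > ratio * sd_act))
    return int(np.sum(sd_ecg >= ratio * sd_act))


# ---------------------------------------------------------------------------
# whole-session analysis
# ---------------------------------------------------------------------------

@dataclass
class TriggerStats:
    """Per-modality trigger fidelity summary (the quantities of the
    trigger-variance table)."""

    modality: str
    interval_mean: float
    interval_sd: float
    offset_mean: float
    offset_sd: float
    jitter: float
    failure_rate: float
    n_cycles: int = 0
    n_missed: int = 0

    def __post_init__(self):
        if self.interval_mean <= 0:
            raise ValidationError("interval_mean must be positive")
        if min(self.interval_sd, self.offset_sd, self.jitter) < 0:
            raise ValidationError("spread statistics must be >= 0")
        if not 0 <= self.failure_rate <= 1:
            raise ValidationError("failure_rate must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "interval_mean_ms": self.interval_mean,
            "interval_sd_ms": self.interval_sd,
            "offset_mean_ms": self.offset_mean,
            "offset_sd_ms": self.offset_sd,
            "jitter_ms": self.jitter,
            "failure_rate": self.failure_rate,
            "n_cycles": self.n_cycles,
            "n_missed": self.n_missed,
        }


def analyze_session(log: PhysioLog, min_hold_s: float = 5.0):
    """Run the full fidelity pipeline on a logged session.

    Returns ``(stats, per_cycle)``: a ``{modality: TriggerStats}`` mapping
    and a ``{modality: CycleOffsets}`` mapping of the per-cycle offsets the
    statistics were computed from.
    """
    holds = identify_breath_holds(log.channel("RESP"), min_duration_s=min_hold_s)
    seg = segment_rr(log.channel("ECG"), holds)
    stats, per_cycle = {}, {}
    for modality, train in log.triggers.items():
        offs = reassign_tickmarks(seg, train)
        per_cycle[modality] = offs
        # intervals are pooled within holds; gaps between holds are not cycles
        intervals = []
        for h in holds:
            in_hold = train.times[(train.times >= h.start) & (train.times <= h.end)]
            if in_hold.size >= 2:
                intervals.extend(np.diff(in_hold) * 1000.0)
        intervals = np.asarray(intervals)
        if intervals.size >= 2:
            iv_mean = float(np.mean(intervals))
            iv_sd = float(np.std(intervals, ddof=1))
        else:
            iv_mean, iv_sd = np.nan, np.nan
        off_mean, off_sd = trigger_offset_stats(offs)
        stats[modality] = TriggerStats(
            modality=modality,
            interval_mean=iv_mean,
            interval_sd=iv_sd,
            offset_mean=off_mean,
            offset_sd=off_sd,
            jitter=trigger_jitter(offs),
            failure_rate=failure_rate(offs),
            n_cycles=seg.n,
            n_missed=offs.n_missed,
        )
    return stats, per_cycle


def _in_any_hold(times: np.ndarray, holds) -> np.ndarray:
    mask = np.zeros(times.size, dtype=bool)
    for h in holds:
        mask |= (times >= h.start) & (times <= h.end)
    return mask


def load_table1(path=None) -> pd.DataFrame:
    """Per-subject trigger-variance table (packaged fixture by default)."""
    if path is None:
        from importlib.resources import files
        path = files("cardiogate.data") / "table1.csv"
    return pd.read_csv(path)
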