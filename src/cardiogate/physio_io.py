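"""Reading and writing of physiological session logs.

A session is stored in a plain-text, UTF-8 encoded log holding a metadata
header, one block per recorded channel and one block per trigger train::

    # meta field_position=isocenter tr_s=0.004 te_s=0.002 subject=s01
    # channel=ECG rate_hz=400 t0_s=0 units=mV
    0.012
    ...
    # triggers=ACT
    1.031

All numbers use ``.`` as the decimal separator irrespective of locale.
Channel samples are written with the shortest representation that
round-trips a double; trigger instants are stored in seconds with
millisecond precision.  The microphone channel may alternatively live in a
single-channel WAV file and is converted to pascal on read via a
calibration constant.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from .exceptions import FormatError, UnsupportedFormatError, ValidationError

__all__ = [
    "CHANNEL_LABELS",
    "TRIGGER_MODALITIES",
    "FIELD_POSITIONS",
    "ChannelTrace",
    "TriggerTrain",
    "SessionMeta",
    "PhysioLog",
    "read_physio_log",
    "write_physio_log",
    "read_mic_wav",
    "write_mic_wav",
]

#: Channel labels in canonical (file-layout) order.
CHANNEL_LABELS = ("ECG", "POX", "ACT", "RESP", "MIC")

#: Modalities for which the monitoring unit emits trigger tickmarks.
TRIGGER_MODALITIES = ("ECG", "POX", "ACT")

#: Named patient-table positions and the static field at the sensors (tesla).
FIELD_POSITIONS = {"home": 0.3, "front": 1.0, "isocenter": 7.0}

_DEFAULT_UNITS = {"ECG": "mV", "POX": "au", "ACT": "au", "RESP": "au", "MIC": "Pa"}


@dataclass
class ChannelTrace:
    """A uniformly sampled single-channel recording on the session clock."""

    label: str
    rate: float
    samples: np.ndarray
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        if self.label not in CHANNEL_LABELS:
            raise ValidationError(f"unknown channel label {self.label!r}")
        if not self.rate > 0:
            raise ValidationError(f"rate must be positive, got {self.rate}")
        if self.t0 < 0:
            raise ValidationError(f"t0 must be non-negative, got {self.t0}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not self.units:
            self.units = _DEFAULT_UNITS[self.label]

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the recording in seconds (n / rate)."""
        return self.samples.size / self.rate

    @property
    def end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        """Session-clock time of every sample."""
        return self.t0 + np.arange(self.samples.size) / self.rate


def _quantize_ms(times) -> np.ndarray:
    # parse-of-print quantization keeps write/read round trips exact
    return np.asarray([float(f"{float(t):.3f}") for t in np.atleast_1d(np.asarray(times, dtype=float))])


@dataclass
class TriggerTrain:
    """Ordered trigger tickmark instants for one modality.

    Times are kept in seconds with millisecond precision, matching the
    resolution at which trigger statistics are reported.
    """

    modality: str
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in TRIGGER_MODALITIES:
            raise ValidationError(f"unknown trigger modality {self.modality!r}")
        self.times = _quantize_ms(self.times) if np.size(self.times) else np.empty(0)
        if self.times.size:
            if np.any(self.times < 0):
                raise ValidationError("trigger times must be non-negative")
            if np.any(np.diff(self.times) <= 0):
                raise ValidationError(
                    f"{self.modality} trigger times must be strictly increasing"
                )

    @property
    def n(self) -> int:
        return self.times.size


@dataclass
class SessionMeta:
    """Session-level acquisition metadata."""

    field_position: str = "isocenter"
    tr_s: float = 0.004
    te_s: float = 0.002
    subject: str = "anon"

    def __post_init__(self) -> None:
        if self.field_position not in FIELD_POSITIONS:
            raise ValidationError(
                f"field_position must be one of {sorted(FIELD_POSITIONS)}, "
                f"got {self.field_position!r}"
            )

    @property
    def field_tesla(self) -> float:
        return FIELD_POSITIONS[self.field_position]


@dataclass
class PhysioLog:
    """A full multi-channel session: traces, trigger trains and metadata."""

    channels: dict = field(default_factory=dict)
    triggers: dict = field(default_factory=dict)
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        for label, trace in self.channels.items():
            if trace.label != label:
                raise ValidationError(
                    f"channel key {label!r} does not match trace label {trace.label!r}"
                )
        for modality, train in self.triggers.items():
            if train.modality != modality:
                raise ValidationError(
                    f"trigger key {modality!r} does not match train modality "
                    f"{train.modality!r}"
                )
        if self.channels:
            start = min(tr.t0 for tr in self.channels.values())
            end = max(tr.end for tr in self.channels.values())
            for train in self.triggers.values():
                if train.times.size and (
                    train.times[0] < start or train.times[-1] > end
                ):
                    raise ValidationError(
                        f"{train.modality} triggers fall outside the recorded span "
                        f"[{start}, {end}]"
                    )

    def channel(self, label: str) -> ChannelTrace:
        try:
            return self.channels[label]
        except KeyError:
            raise KeyError(f"log has no {label!r} channel") from None


# ---------------------------------------------------------------------------
# text log format
# ---------------------------------------------------------------------------

def _parse_kv(tokens, where):
    out = {}
    for tok in tokens:
        if "=" not in tok:
            raise FormatError(f"malformed key=value token {tok!r} in {where}")
        key, _, val = tok.partition("=")
        out[key] = val
    return out


def read_physio_log(path) -> PhysioLog:
    """Parse a text session log into a :class:`PhysioLog`.

    Raises :class:`FormatError` for structural problems (unknown labels,
    duplicate channels, malformed headers) and :class:`ValidationError`
    when the content violates domain invariants (e.g. non-monotone trigger
    times).
    """
    channels: dict = {}
    triggers: dict = {}
    meta_kwargs: dict = {}
    current: list | None = None  # sample accumulator of the open block
    pending = None  # ("channel"|"triggers", header dict)

    def close_block():
        nonlocal current, pending
        if pending is None:
            return
        kind, hdr = pending
        values = np.asarray(current, dtype=float)
        if kind == "channel":
            label = hdr["channel"]
            if label in channels:
                raise FormatError(f"duplicate channel block for {label!r}")
            if label not in CHANNEL_LABELS:
                raise FormatError(f"unknown channel label {label!r}")
            channels[label] = ChannelTrace(
                label=label,
                rate=float(hdr["rate_hz"]),
                t0=float(hdr.get("t0_s", 0.0)),
                units=hdr.get("units", ""),
                samples=values,
            )
        else:
            modality = hdr["triggers"]
            if modality in triggers:
                raise FormatError(f"duplicate trigger block for {modality!r}")
            if modality not in TRIGGER_MODALITIES:
                raise FormatError(f"unknown trigger modality {modality!r}")
            triggers[modality] = TriggerTrain(modality=modality, times=values)
        current, pending = None, None

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                close_block()
                tokens = line[1:].split()
                if not tokens:
                    raise FormatError(f"empty header at line {lineno}")
                if tokens[0] == "meta":
                    kv = _parse_kv(tokens[1:], f"line {lineno}")
                    meta_kwargs = {
                        "field_position": kv.get("field_position", "isocenter"),
                        "tr_s": float(kv.get("tr_s", 0.004)),
                        "te_s": float(kv.get("te_s", 0.002)),
                        "subject": kv.get("subject", "anon"),
                    }
                elif tokens[0].startswith("channel="):
                    kv = _parse_kv(tokens, f"line {lineno}")
                    if "rate_hz" not in kv:
                        raise FormatError(f"channel header missing rate_hz at line {lineno}")
                    pending, current = ("channel", kv), []
                elif tokens[0].startswith("triggers="):
                    kv = _parse_kv(tokens, f"line {lineno}")
                    pending, current = ("triggers", kv), []
                else:
                    raise FormatError(f"unrecognized header {line!r} at line {lineno}")
            else:
                if current is None:
                    raise FormatError(f"data outside any block at line {lineno}")
                try:
                    current.append(float(line))
                except ValueError:
                    raise FormatError(f"non-numeric sample {line!r} at line {lineno}") from None
        close_block()

    return PhysioLog(channels=channels, triggers=triggers, meta=SessionMeta(**meta_kwargs))


def write_physio_log(log: PhysioLog, path) -> None:
    """Serialize ``log`` so that :func:`read_physio_log` recovers it exactly.

    Layout is deterministic: metadata first, channels in canonical label
    order, trigger trains in modality order.
    """
    m = log.meta
    lines = [
        f"# meta field_position={m.field_position} tr_s={m.tr_s!r} "
        f"te_s={m.te_s!r} subject={m.subject}"
    ]
    for label in CHANNEL_LABELS:
        if label not in log.channels:
            continue
        tr = log.channels[label]
        lines.append(
            f"# channel={label} rate_hz={tr.rate!r} t0_s={tr.t0!r} units={tr.units}"
        )
        lines.extend(repr(v) for v in tr.samples.tolist())
    for modality in TRIGGER_MODALITIES:
        if modality not in log.triggers:
            continue
        lines.append(f"# triggers={modality}")
        lines.extend(f"{t:.3f}" for t in log.triggers[modality].times.tolist())
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# WAV microphone channel
# ---------------------------------------------------------------------------

_PCM_FULL_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31,
                   np.dtype(np.uint8): 2**7}


def read_mic_wav(path, calibration: float = 1.0, t0: float = 0.0) -> ChannelTrace:
    """Read a single-channel WAV file as a microphone trace in pascal.

    ``calibration`` is the Pa-per-full-scale-unit constant obtained from
    :func:`cardiogate.acoustics.calibrate_spl`.  PCM data are normalized to
    [-1, 1) before scaling; float data are used as-is.
    """
    rate, data = wavfile.read(os.fspath(path))
    if data.ndim != 1:
        raise UnsupportedFormatError(
            f"expected a single-channel WAV, got {data.shape[1]} channels"
        )
    if data.dtype.kind in "iu":
        scale = _PCM_FULL_SCALE.get(data.dtype)
        if scale is None:
            raise UnsupportedFormatError(f"unsupported PCM dtype {data.dtype}")
        if data.dtype == np.uint8:
            samples = (data.astype(float) - 128.0) / scale
        else:
            samples = data.astype(float) / scale
    elif data.dtype.kind == "f":
        samples = data.astype(float)
    else:
        raise UnsupportedFormatError(f"unsupported WAV dtype {data.dtype}")
    return ChannelTrace(label="MIC", rate=float(rate), t0=t0,
                        samples=samples * calibration, units="Pa")


def write_mic_wav(trace: ChannelTrace, path, calibration: float = 1.0) -> None:
    """Write a microphone trace as a float32 WAV (inverse of :func:`read_mic_wav`)."""
    data = (trace.samples / calibration).astype(np.float32)
    wavfile.write(os.fspath(path), int(round(trace.rate)), data)
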