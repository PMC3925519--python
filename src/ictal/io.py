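"""Record containers and readers/writers for the supported EEG formats.

Three on-disk formats are supported:

* single-column ASCII (one sample per line) for Bonn-style single-channel
  segments, conventionally 4096 samples at 173.61 Hz;
* EDF (European Data Format) for CHB-style multichannel records, read through
  :mod:`mne`; a minimal 16-bit EDF writer is provided so synthetic records can
  round-trip through the same reader;
* a CSV sidecar (``record_id,seizure_start_s,seizure_end_s``) for seizure
  annotations, seconds from record start, half-open ``[start, end)``.

Every reader rejects malformed input with a descriptive error rather than
silently coercing it.
"""

from __future__ import annotations

import csv
import datetime as _dt
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EegRecord",
    "BONN_SAMPLING_RATE_HZ",
    "CHB_SAMPLING_RATE_HZ",
    "read_bonn_ascii",
    "write_bonn_ascii",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
]

BONN_SAMPLING_RATE_HZ = 173.61
CHB_SAMPLING_RATE_HZ = 256.0


@dataclass
class EegRecord:
    """Multichannel EEG samples with sampling rate and optional annotations.

    ``samples`` is a (channels, time) float array in microvolt-scale units;
    ``annotations`` is a sorted list of non-overlapping seizure intervals
    ``(start_s, end_s)``, half-open, in seconds from record start.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channel_labels: tuple[str, ...] = ()
    record_id: str = ""
    annotations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = tuple(
                f"ch{i + 1}" for i in range(self.samples.shape[0])
            )
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        self.annotations = validate_intervals(self.annotations, self.duration_s)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, index: int) -> np.ndarray:
        return self.samples[index]


def validate_intervals(
    intervals, duration_s: float | None = None
) -> list[tuple[float, float]]:
    """Sort intervals, then reject empty, overlapping or out-of-range ones."""
    out = sorted((float(a), float(b)) for a, b in intervals)
    prev_end = -np.inf
    for start, end in out:
        if end <= start:
            raise ValueError(f"interval ({start}, {end}) has end <= start")
        if start < prev_end:
            raise ValueError(f"interval ({start}, {end}) overlaps its predecessor")
        if duration_s is not None and (start < 0 or end > duration_s + 1e-9):
            raise ValueError(
                f"interval ({start}, {end}) outside record of {duration_s:.2f} s"
            )
        prev_end = end
    return out


# ---------------------------------------------------------------------------
# Bonn-style single-column ASCII
# ---------------------------------------------------------------------------

def read_bonn_ascii(path) -> EegRecord:
    """Read a single-channel ASCII record (one numeric sample per line)."""
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path.name}: non-numeric sample {text!r} on line {lineno}"
                ) from None
    if not values:
        raise ValueError(f"{path.name}: no samples found")
    return EegRecord(
        samples=np.asarray(values)[None, :],
        sampling_rate_hz=BONN_SAMPLING_RATE_HZ,
        record_id=path.stem,
    )


def write_bonn_ascii(record: EegRecord, path) -> None:
    """Write the first channel as one sample per line (integers stay integral)."""
    x = record.samples[0]
    with open(path, "w") as fh:
        for v in x:
            fh.write(f"{int(round(v))}\n" if float(v).is_integer() else f"{v}\n")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_header_sample_rates(path) -> list[float]:
    """Per-signal sampling rates from the EDF header (for the mixed-rate check)."""
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise ValueError(f"{Path(path).name}: truncated EDF header")
        duration = float(fixed[244:252].decode("ascii"))
        ns = int(fixed[252:256].decode("ascii"))
        per_signal = fh.read(ns * 256)
        offset = ns * 216  # after label/transducer/dim/phys/dig/prefilter fields
        rates = []
        for i in range(ns):
            n_samp = int(per_signal[offset + 8 * i : offset + 8 * (i + 1)].decode("ascii"))
            rates.append(n_samp / duration)
    return rates


def read_edf(path) -> EegRecord:
    """Read a multichannel EDF record via mne.

    All signals must share one sampling rate; mixed-rate files are refused
    (the targeted recordings are uniformly 256 Hz) rather than resampled.
    Amplitudes are returned in microvolts.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rates = _edf_header_sample_rates(path)
    if len(set(rates)) > 1:
        raise ValueError(
            f"{path.name}: mixed per-channel sampling rates {sorted(set(rates))}; "
            "resampling is refused"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return EegRecord(
        samples=np.asarray(data, dtype=np.float64),
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        record_id=path.stem,
    )


def write_edf(record: EegRecord, path) -> None:
    """Write a record as 16-bit EDF with 1-second data records.

    Deliberately minimal: one common integer sampling rate, EEG channels in
    microvolts, no embedded annotations (those travel in the CSV sidecar).
    Samples are quantised to the 16-bit grid spanning the per-channel
    amplitude range, the same resolution as the targeted recordings.
    """
    rate = record.sampling_rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))
    x = record.samples
    n_ch, n_samp = x.shape
    n_records = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samp] = x

    phys_min = np.floor(np.minimum(padded.min(axis=1), -1.0))
    phys_max = np.ceil(np.maximum(padded.max(axis=1), 1.0))
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r}")
        return b.ljust(width)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f(f"Startdate X X X X {record.record_id or 'record'}"[:80], 80),
            f(now.strftime("%d.%m.%y"), 8),
            f(now.strftime("%H.%M.%S"), 8),
            f(str(256 * (1 + n_ch)), 8),
            f("", 44),
            f(str(n_records), 8),
            f("1", 8),
            f(str(n_ch), 4),
        ]
    )
    labels = [lab[:16] for lab in record.channel_labels]
    header += b"".join(f(lab, 16) for lab in labels)
    header += b"".join(f("", 80) for _ in labels)
    header += b"".join(f("uV", 8) for _ in labels)
    header += b"".join(f(f"{v:g}"[:8], 8) for v in phys_min)
    header += b"".join(f(f"{v:g}"[:8], 8) for v in phys_max)
    header += b"".join(f(str(dig_min), 8) for _ in labels)
    header += b"".join(f(str(dig_max), 8) for _ in labels)
    header += b"".join(f("", 80) for _ in labels)
    header += b"".join(f(str(spr), 8) for _ in labels)
    header += b"".join(f("", 32) for _ in labels)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# Annotation CSV sidecar
# ---------------------------------------------------------------------------

_ANNOTATION_HEADER = ["record_id", "seizure_start_s", "seizure_end_s"]


def read_annotations(path) -> dict[str, list[tuple[float, float]]]:
    """Read seizure intervals keyed by record id from the CSV sidecar."""
    path = Path(path)
    out: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _ANNOTATION_HEADER:
            raise ValueError(
                f"{path.name}: expected header {','.join(_ANNOTATION_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != 3:
                raise ValueError(f"{path.name}: malformed row on line {lineno}")
            rid, start, end = row[0].strip(), float(row[1]), float(row[2])
            out.setdefault(rid, []).append((start, end))
    return {rid: validate_intervals(iv) for rid, iv in out.items()}


def write_annotations(annotations: dict[str, list[tuple[float, float]]], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOTATION_HEADER)
        for rid in annotations:
            for start, end in annotations[rid]:
                writer.writerow([rid, f"{start:g}", f"{end:g}"])
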