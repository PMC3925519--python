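"""Seeded synthetic EEG generators for both pipeline flavours.

Two record families are emulated so every stage is testable without any
external archive:

* **Bonn-like** single-channel segments: 4096 samples at 173.61 Hz, integer
  amplitudes (12-bit acquisition), in three regimes —

  ``bonn_normal``
      band-limited (0.53-40 Hz) background noise at baseline amplitude
      (sigma ~ 50 uV), the awake eyes-open surface recording;
  ``bonn_interictal``
      delta-dominant background (seizure-free epileptogenic-zone activity
      carries more slow-wave power) plus sparse isolated spikes at ~8x the
      baseline amplitude;
  ``bonn_ictal``
      sustained ~3 Hz spike-wave discharge at >= 10x baseline amplitude, the
      classic generalised ictal rhythm.

  The amplitude contrasts are calibrated so subband feature magnitudes land
  within about an order of magnitude of values reported for the real sets
  (e.g. A4 standard deviation ~ 10^2 for normal vs ~ 10^3 for ictal
  segments), without attempting exact reproduction.

* **CHB-like** multichannel records: 23 channels at 256 Hz with annotated
  seizure intervals during which >= 70% of channels (80% by default) carry
  the ictal pattern, so a 60%-of-channels vote can fire.

Identical ``SynthSpec`` (same seed included) always yields identical samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import (
    BONN_SAMPLING_RATE_HZ,
    CHB_SAMPLING_RATE_HZ,
    EegRecord,
    validate_intervals,
)

__all__ = [
    "SynthSpec",
    "generate_bonn_like",
    "generate_chb_like",
    "generate_bonn_set",
    "generate_chb_patient",
    "BONN_MODES",
]

BONN_MODES = ("bonn_normal", "bonn_interictal", "bonn_ictal")

# Amplitude palette (microvolt-scale), chosen once; see the methods note.
_BASELINE_STD = 50.0
_INTERICTAL_DELTA_STD = 120.0
_INTERICTAL_SPIKE_AMP = 400.0
_INTERICTAL_SPIKE_RATE_HZ = 1.0
_ICTAL_WAVE_AMP = 550.0
_ICTAL_SPIKE_AMP = 700.0
_ICTAL_NOISE_STD = 100.0
_SPIKE_WAVE_HZ = 3.0
_CHB_ICTAL_CHANNEL_FRACTION = 0.8


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic record."""

    mode: str
    seed: int
    n_channels: int = 1
    sampling_rate_hz: float = BONN_SAMPLING_RATE_HZ
    duration_s: float = 4096 / BONN_SAMPLING_RATE_HZ
    seizure_intervals: tuple[tuple[float, float], ...] = ()
    amplitude_scale: float = 1.0
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.mode in BONN_MODES and self.seizure_intervals:
            raise ValueError("seizure_intervals apply to chb_record mode only")
        validate_intervals(self.seizure_intervals, self.duration_s)


def _bandpass_noise(rng, n, fs, lo=0.53, hi=40.0, order=4) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 512))[256:-256]
    return x / max(x.std(), 1e-12)


def _mexican_hat(fs, width_s=0.06) -> np.ndarray:
    """Unit-peak biphasic spike kernel (second Gaussian derivative)."""
    half = int(round(3 * width_s * fs))
    t = np.arange(-half, half + 1) / fs
    u = t / width_s
    return (1 - u**2) * np.exp(-(u**2) / 2)


def _spike_train(rng, n, fs, rate_hz, amp) -> np.ndarray:
    """Poisson-timed spikes of random polarity-free amplitude jitter."""
    kernel = _mexican_hat(fs)
    x = np.zeros(n)
    n_spikes = rng.poisson(rate_hz * n / fs)
    positions = np.sort(rng.integers(0, n, size=n_spikes))
    impulses = np.zeros(n)
    for p in positions:
        impulses[p] += amp * rng.uniform(0.7, 1.3)
    x = np.convolve(impulses, kernel, mode="same")
    return x


def _spike_wave(rng, n, fs, wave_amp, spike_amp) -> np.ndarray:
    """~3 Hz spike-wave discharge with slow amplitude modulation."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.1, 0.3) * t + phase)
    wave = wave_amp * np.sin(2 * np.pi * _SPIKE_WAVE_HZ * t + phase)
    # one sharp transient per slow-wave cycle
    period = int(round(fs / _SPIKE_WAVE_HZ))
    impulses = np.zeros(n)
    start = int(rng.integers(0, period))
    for p in range(start, n, period):
        impulses[p] = spike_amp * rng.uniform(0.8, 1.2)
    spikes = np.convolve(impulses, _mexican_hat(fs, width_s=0.035), mode="same")
    return envelope * (wave + spikes)


def _bonn_channel(mode: str, rng, n: int, fs: float, scale: float) -> np.ndarray:
    if mode == "bonn_normal":
        x = _BASELINE_STD * _bandpass_noise(rng, n, fs)
    elif mode == "bonn_interictal":
        x = (
            _INTERICTAL_DELTA_STD * _bandpass_noise(rng, n, fs, lo=0.53, hi=4.0)
            + 0.6 * _BASELINE_STD * _bandpass_noise(rng, n, fs)
            + _spike_train(rng, n, fs, _INTERICTAL_SPIKE_RATE_HZ, _INTERICTAL_SPIKE_AMP)
        )
    elif mode == "bonn_ictal":
        x = _spike_wave(rng, n, fs, _ICTAL_WAVE_AMP, _ICTAL_SPIKE_AMP)
        x += _ICTAL_NOISE_STD * _bandpass_noise(rng, n, fs)
    else:
        raise ValueError(f"unknown Bonn-like mode {mode!r}; use one of {BONN_MODES}")
    return scale * x


def generate_bonn_like(spec: SynthSpec) -> EegRecord:
    """One single-channel Bonn-like segment; samples rounded to integers."""
    if spec.mode not in BONN_MODES:
        raise ValueError(f"unknown Bonn-like mode {spec.mode!r}; use one of {BONN_MODES}")
    if spec.n_channels != 1:
        raise ValueError("Bonn-like records are single-channel")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sampling_rate_hz))
    x = _bonn_channel(spec.mode, rng, n, spec.sampling_rate_hz, spec.amplitude_scale)
    return EegRecord(
        samples=np.rint(x)[None, :],
        sampling_rate_hz=spec.sampling_rate_hz,
        record_id=spec.record_id or f"{spec.mode}_{spec.seed}",
    )


def generate_chb_like(spec: SynthSpec) -> EegRecord:
    """A CHB-like multichannel record with annotated seizure intervals.

    Background is baseline band-limited noise per channel; inside each
    seizure interval a high-amplitude spike-wave pattern is added on a fixed
    random subset of >= 70% of the channels (80% by default), with
    channel-specific phase, so epoch-wise channel voting can reach the 60%
    threshold.
    """
    if spec.mode != "chb_record":
        raise ValueError(f"expected mode 'chb_record', got {spec.mode!r}")
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))
    c = spec.n_channels
    samples = np.empty((c, n))
    for ch in range(c):
        samples[ch] = _BASELINE_STD * _bandpass_noise(rng, n, fs)
    n_ictal_ch = max(1, math.ceil(_CHB_ICTAL_CHANNEL_FRACTION * c))
    for start_s, end_s in spec.seizure_intervals:
        i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
        ictal_channels = rng.choice(c, size=n_ictal_ch, replace=False)
        for ch in ictal_channels:
            samples[ch, i0:i1] += _spike_wave(
                rng, i1 - i0, fs, _ICTAL_WAVE_AMP, _ICTAL_SPIKE_AMP
            )
    samples *= spec.amplitude_scale
    return EegRecord(
        samples=samples,
        sampling_rate_hz=fs,
        record_id=spec.record_id or f"chb_{spec.seed}",
        annotations=list(spec.seizure_intervals),
    )


def generate_bonn_set(mode: str, n_records: int, seed: int) -> list[EegRecord]:
    """``n_records`` independent Bonn-like segments of one regime.

    Record seeds are derived from ``seed`` so sets for different regimes or
    base seeds never share streams.
    """
    root = np.random.default_rng([seed, BONN_MODES.index(mode)])
    seeds = root.integers(0, 2**31 - 1, size=n_records)
    return [
        generate_bonn_like(
            SynthSpec(mode=mode, seed=int(s), record_id=f"{mode}_{i:03d}")
        )
        for i, s in enumerate(seeds)
    ]


def generate_chb_patient(
    patient_id: str,
    n_seizures: int,
    seed: int,
    n_channels: int = 23,
    record_duration_s: float = 60.0,
    seizure_interval: tuple[float, float] = (20.0, 35.0),
    n_background_records: int | None = None,
) -> list[EegRecord]:
    """A synthetic patient: one seizure record per seizure plus background records.

    Each seizure record carries one annotated seizure; background records are
    seizure-free and supply normal training epochs.  Their count defaults to
    enough records that matched normal epochs exist for every training
    seizure epoch.
    """
    if n_seizures < 1:
        raise ValueError("a patient needs at least one seizure")
    seizure_epochs = int(seizure_interval[1] - seizure_interval[0])
    record_epochs = int(record_duration_s)
    if n_background_records is None:
        needed = math.ceil(0.6 * n_seizures) * seizure_epochs
        n_background_records = max(2, math.ceil(needed / record_epochs))
    root = np.random.default_rng([seed, 917])
    records = []
    for i in range(n_seizures):
        records.append(
            generate_chb_like(
                SynthSpec(
                    mode="chb_record",
                    seed=int(root.integers(0, 2**31 - 1)),
                    n_channels=n_channels,
                    sampling_rate_hz=CHB_SAMPLING_RATE_HZ,
                    duration_s=record_duration_s,
                    seizure_intervals=(seizure_interval,),
                    record_id=f"{patient_id}_sz{i:02d}",
                )
            )
        )
    for i in range(n_background_records):
        records.append(
            generate_chb_like(
                SynthSpec(
                    mode="chb_record",
                    seed=int(root.integers(0, 2**31 - 1)),
                    n_channels=n_channels,
                    sampling_rate_hz=CHB_SAMPLING_RATE_HZ,
                    duration_s=record_duration_s,
                    record_id=f"{patient_id}_bg{i:02d}",
                )
            )
        )
    return records
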