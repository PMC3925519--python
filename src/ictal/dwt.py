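"""Filter-bank discrete wavelet decomposition with Daubechies order-2 wavelets.

The decomposition is the classic two-channel analysis bank: at each stage the
running approximation is passed through a low-pass filter ``h`` and its
quadrature-mirror high-pass ``g``, each followed by dyadic downsampling.  The
detail outputs D1..Dl and the final approximation A_l together cover the
signal's frequency axis in octave bands; for EEG sampled near 173 Hz a 4-level
db2 decomposition places D3, D4 and A4 over the clinically interesting
sub-40 Hz range.

Boundary handling follows the conventions of mainstream wavelet toolboxes so
that coefficients are reproducible bit-for-bit across implementations:

``symmetric`` (default)
    half-point symmetric extension by ``L - 1`` samples on each side; output
    length ``floor((n + L - 1) / 2)``.
``zero``
    zero padding, same output length as ``symmetric``.
``periodization``
    periodic extension (odd-length inputs are first padded by repeating the
    last sample); output length ``ceil(n / 2)``.  This mode is orthogonal for
    even lengths, so energy is conserved and the transform is exactly
    invertible.

All operations accept arrays of shape ``(..., n)`` and transform along the
last axis, so a batch of frames is decomposed in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "WaveletFilterPair",
    "SubbandSet",
    "db2_filters",
    "dwt_single_level",
    "idwt_single_level",
    "decompose",
    "EXTENSION_MODES",
]

EXTENSION_MODES = ("symmetric", "periodization", "zero")

# Standard Daubechies-2 scaling coefficients, (1±√3)/(4√2) etc., hard-coded to
# 16 significant digits for determinism rather than re-derived at runtime.
_DB2_LOWPASS = (
    0.4829629131445341,
    0.8365163037378079,
    0.2241438680420134,
    -0.1294095225512604,
)


@dataclass(frozen=True)
class WaveletFilterPair:
    """Analysis filter pair (low-pass ``h``, high-pass ``g``) of a wavelet.

    The high-pass filter is the quadrature mirror of the low-pass one:
    ``g[k] = (-1)**k * h[L - 1 - k]``.
    """

    lowpass: tuple[float, ...]
    highpass: tuple[float, ...]
    name: str = "db2"

    def __post_init__(self) -> None:
        if len(self.lowpass) != len(self.highpass):
            raise ValueError("lowpass and highpass must have equal length")

    def __len__(self) -> int:
        return len(self.lowpass)


def db2_filters() -> WaveletFilterPair:
    """Return the standard 4-tap db2 analysis filter pair.

    ``sum(lowpass)`` equals ``sqrt(2)`` (admissibility) and ``sum(highpass)``
    equals 0 (vanishing moment), both to near machine precision.
    """
    h = _DB2_LOWPASS
    L = len(h)
    g = tuple((-1.0) ** k * h[L - 1 - k] for k in range(L))
    return WaveletFilterPair(lowpass=h, highpass=g, name="db2")


@dataclass
class SubbandSet:
    """Multilevel decomposition result: details D1..Dl plus approximation A_l."""

    details: list[np.ndarray]
    approximation: np.ndarray
    levels: int
    extension_mode: str
    wavelet: str = "db2"

    def detail(self, level: int) -> np.ndarray:
        """Detail coefficients at ``level`` (1-based, D1 = finest scale)."""
        if not 1 <= level <= self.levels:
            raise ValueError(f"level must be in 1..{self.levels}, got {level}")
        return self.details[level - 1]

    def subband(self, name: str) -> np.ndarray:
        """Fetch a band by conventional name, e.g. ``"D3"`` or ``"A4"``."""
        kind, lvl = name[0].upper(), int(name[1:])
        if kind == "D":
            return self.detail(lvl)
        if kind == "A":
            if lvl != self.levels:
                raise ValueError(
                    f"only the final approximation A{self.levels} is retained"
                )
            return self.approximation
        raise ValueError(f"unknown subband {name!r}")

    def energies(self) -> np.ndarray:
        """Per-band energies [D1..Dl, A_l], summed over the last axis."""
        bands = self.details + [self.approximation]
        return np.stack([np.sum(np.square(b), axis=-1) for b in bands])


def _check_mode(extension_mode: str) -> None:
    if extension_mode not in EXTENSION_MODES:
        raise ValueError(
            f"extension_mode must be one of {EXTENSION_MODES}, got {extension_mode!r}"
        )


def _extend(x: np.ndarray, pad: int, extension_mode: str) -> np.ndarray:
    if extension_mode == "zero":
        return np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)])
    if extension_mode == "symmetric":
        return np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="symmetric")
    # periodization: odd lengths are padded by repeating the final sample first
    if x.shape[-1] % 2:
        x = np.concatenate([x, x[..., -1:]], axis=-1)
    return np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="wrap")


def dwt_single_level(
    signal: Sequence[float] | np.ndarray,
    filters: WaveletFilterPair | None = None,
    extension_mode: str = "symmetric",
) -> tuple[np.ndarray, np.ndarray]:
    """One analysis stage: filter with (h, g) and downsample by two.

    Parameters
    ----------
    signal
        Real array, shape ``(..., n)``; transformed along the last axis.
    filters
        Analysis pair; defaults to :func:`db2_filters`.
    extension_mode
        One of ``symmetric``, ``periodization``, ``zero``.

    Returns
    -------
    (approximation, detail)
        Low-pass and high-pass subband coefficients.
    """
    _check_mode(extension_mode)
    if filters is None:
        filters = db2_filters()
    x = np.asarray(signal, dtype=np.float64)
    n = x.shape[-1]
    if n == 0:
        raise ValueError("cannot transform an empty signal")
    h = np.asarray(filters.lowpass)
    g = np.asarray(filters.highpass)
    L = len(h)
    ext = _extend(x, L - 1, extension_mode)
    windows = sliding_window_view(ext, L, axis=-1)
    if extension_mode == "periodization":
        n_out = (n + 1) // 2
        windows = windows[..., 2::2, :][..., :n_out, :]
    else:
        windows = windows[..., 1::2, :]
    return windows @ h, windows @ g


def idwt_single_level(
    approximation: np.ndarray,
    detail: np.ndarray,
    filters: WaveletFilterPair | None = None,
    extension_mode: str = "periodization",
    output_length: int | None = None,
) -> np.ndarray:
    """Invert one analysis stage (periodization mode only).

    Periodization is the orthogonal circulant case, so synthesis is the exact
    transpose of analysis: every coefficient scatters its filter taps back
    onto the circle.  ``output_length`` trims the trailing pad sample when the
    original signal length was odd.
    """
    if extension_mode != "periodization":
        raise NotImplementedError(
            "exact inversion is implemented for periodization mode only"
        )
    if filters is None:
        filters = db2_filters()
    a = np.asarray(approximation, dtype=np.float64)
    d = np.asarray(detail, dtype=np.float64)
    if a.shape != d.shape:
        raise ValueError("approximation and detail must have matching shapes")
    h = np.asarray(filters.lowpass)
    g = np.asarray(filters.highpass)
    L = len(h)
    m = 2 * a.shape[-1]
    x = np.zeros(a.shape[:-1] + (m,))
    idx = np.arange(a.shape[-1])
    for k in range(L):
        # analysis window i covered samples (2i + k - 1) mod m
        pos = (2 * idx + k - 1) % m
        np.add.at(x, (..., pos), a * h[k])
        np.add.at(x, (..., pos), d * g[k])
    if output_length is not None:
        x = x[..., :output_length]
    return x


def decompose(
    signal: Sequence[float] | np.ndarray,
    levels: int = 4,
    extension_mode: str = "symmetric",
    filters: WaveletFilterPair | None = None,
) -> SubbandSet:
    """Multilevel decomposition: iterate the analysis stage on the approximation.

    Raises
    ------
    ValueError
        If ``levels < 1`` or the running approximation becomes shorter than
        the filter at some level (the error names the failing level).
    """
    _check_mode(extension_mode)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if filters is None:
        filters = db2_filters()
    a = np.asarray(signal, dtype=np.float64)
    if a.shape[-1] == 0:
        raise ValueError("cannot decompose an empty signal")
    details: list[np.ndarray] = []
    for lvl in range(1, levels + 1):
        if a.shape[-1] < len(filters):
            raise ValueError(
                f"signal too short for level {lvl}: approximation has "
                f"{a.shape[-1]} samples, filter needs {len(filters)}"
            )
        a, d = dwt_single_level(a, filters, extension_mode)
        details.append(d)
    return SubbandSet(
        details=details,
        approximation=a,
        levels=levels,
        extension_mode=extension_mode,
        wavelet=filters.name,
    )
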