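"""Subband and raw-epoch feature extraction for seizure detection.

Six statistics are computed on each retained wavelet subband (D3, D4, A4):
maximum, minimum, mean, sample standard deviation (N-1 denominator), a
non-normalised energy-weighted entropy sum(c^2 * ln(c^2)) with the
0*ln(0) = 0 convention, and energy sum(|c|^2).  For onset detection two raw
statistics are appended, computed on the undecomposed epoch samples: the
interquartile range (Q3 - Q1, linear-interpolation quantiles) and the mean
absolute deviation from the mean.

The feature order is frozen so serialized models are portable:
``[max, min, mean, std, entropy, energy]`` for each of ``[D3, D4, A4]``
(18 values), then ``[IQR, MAD]`` (20 values for onset vectors).

All scalar feature functions accept arrays of shape ``(..., n)`` and reduce
along the last axis, so a stack of frames is featurised in one vectorised
call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dwt import decompose

__all__ = [
    "FeatureVector",
    "EVENT_FEATURE_NAMES",
    "ONSET_FEATURE_NAMES",
    "subband_energy",
    "subband_entropy",
    "subband_stats",
    "iqr",
    "mad",
    "event_feature_vector",
    "onset_channel_features",
    "event_feature_matrix",
    "onset_feature_matrix",
    "feature_table",
]

_SUBBANDS = ("D3", "D4", "A4")
_STAT_NAMES = ("max", "min", "mean", "std", "entropy", "energy")

EVENT_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{band}_{stat}" for band in _SUBBANDS for stat in _STAT_NAMES
)
ONSET_FEATURE_NAMES: tuple[str, ...] = EVENT_FEATURE_NAMES + ("IQR", "MAD")


@dataclass
class FeatureVector:
    """Named, ordered feature values for one frame or channel-epoch."""

    names: tuple[str, ...]
    values: np.ndarray
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != self.values.shape[-1]:
            raise ValueError(
                f"{len(self.names)} names but {self.values.shape[-1]} values"
            )

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


def _as_array(x, min_len: int = 1, what: str = "input") -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.shape[-1] < min_len:
        raise ValueError(f"{what} needs at least {min_len} samples, got {a.shape[-1]}")
    return a


def subband_energy(coeffs) -> np.ndarray | float:
    """Energy sum(|c_j|^2) of a coefficient sequence."""
    c = _as_array(coeffs, 1, "coefficients")
    return np.sum(np.square(c), axis=-1)


def subband_entropy(coeffs) -> np.ndarray | float:
    """Energy-weighted entropy sum(c_j^2 * ln(c_j^2)), with 0*ln(0) = 0.

    Natural logarithm; the quantity is not normalised to a probability
    distribution, so it scales with signal energy and is unbounded.
    """
    c2 = np.square(_as_array(coeffs, 1, "coefficients"))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(c2 > 0, c2 * np.log(np.where(c2 > 0, c2, 1.0)), 0.0)
    return np.sum(terms, axis=-1)


def subband_stats(coeffs) -> tuple:
    """(maximum, minimum, mean, sample std) of a coefficient sequence.

    The standard deviation uses the N-1 denominator; a length-1 input yields
    std 0 with a warning rather than an error.
    """
    c = _as_array(coeffs, 1, "coefficients")
    if c.shape[-1] < 2:
        warnings.warn(
            "standard deviation of a single coefficient reported as 0",
            stacklevel=2,
        )
        std = np.zeros(c.shape[:-1])
        if std.ndim == 0:
            std = std[()]
    else:
        std = np.std(c, axis=-1, ddof=1)
    return (
        np.max(c, axis=-1),
        np.min(c, axis=-1),
        np.mean(c, axis=-1),
        std,
    )


def iqr(samples) -> np.ndarray | float:
    """Interquartile range Q3 - Q1, quartiles by linear interpolation."""
    x = _as_array(samples, 4, "IQR input")
    q1, q3 = np.percentile(x, [25, 75], axis=-1)
    return q3 - q1


def mad(samples) -> np.ndarray | float:
    """Mean absolute deviation from the mean, (1/N) sum|x_j - mean|."""
    x = _as_array(samples, 1, "MAD input")
    return np.mean(np.abs(x - np.mean(x, axis=-1, keepdims=True)), axis=-1)


def _wavelet_feature_block(frames: np.ndarray, dwt_config: dict | None) -> np.ndarray:
    """(..., 18) wavelet features of frames shaped (..., n)."""
    cfg = {"levels": 4, "extension_mode": "symmetric"}
    if dwt_config:
        cfg.update(dwt_config)
    bands = decompose(frames, levels=cfg["levels"], extension_mode=cfg["extension_mode"])
    cols = []
    for name in _SUBBANDS:
        c = bands.subband(name)
        mx, mn, mu, sd = subband_stats(c)
        cols += [mx, mn, mu, sd, subband_entropy(c), subband_energy(c)]
    return np.stack(cols, axis=-1)


def event_feature_matrix(frames, dwt_config: dict | None = None) -> np.ndarray:
    """Vectorised 18-feature extraction for a stack of frames (m, n) -> (m, 18)."""
    return _wavelet_feature_block(np.atleast_2d(np.asarray(frames, float)), dwt_config)


def onset_feature_matrix(epochs, dwt_config: dict | None = None) -> np.ndarray:
    """Vectorised 20-feature extraction for channel-epochs (m, n) -> (m, 20)."""
    x = np.atleast_2d(np.asarray(epochs, float))
    wav = _wavelet_feature_block(x, dwt_config)
    return np.concatenate(
        [wav, iqr(x)[..., None], mad(x)[..., None]], axis=-1
    )


def event_feature_vector(frame, dwt_config: dict | None = None) -> FeatureVector:
    """18 wavelet features of one analysis frame (D3/D4/A4 x six statistics)."""
    values = _wavelet_feature_block(_as_array(frame, 4, "frame"), dwt_config)
    return FeatureVector(names=EVENT_FEATURE_NAMES, values=values)


def onset_channel_features(epoch_channel, dwt_config: dict | None = None) -> FeatureVector:
    """20 features of one channel-epoch: 18 wavelet features plus raw IQR and MAD."""
    x = _as_array(epoch_channel, 4, "epoch")
    values = np.concatenate(
        [
            _wavelet_feature_block(x, dwt_config),
            np.atleast_1d(iqr(x)),
            np.atleast_1d(mad(x)),
        ]
    )
    return FeatureVector(names=ONSET_FEATURE_NAMES, values=values)


def feature_table(
    matrix: np.ndarray,
    names: Sequence[str],
    provenance: dict[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Feature matrix as a DataFrame with provenance columns first.

    ``provenance`` maps column name (e.g. record id, channel, frame index) to
    a sequence of per-row values; these precede the feature columns so the
    table round-trips through CSV with a self-describing header.
    """
    df = pd.DataFrame(np.atleast_2d(matrix), columns=list(names))
    if provenance:
        for i, (col, vals) in enumerate(provenance.items()):
            df.insert(i, col, list(vals))
    return df
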