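"""Stationary (undecimated) Haar wavelet transform of encoded series.

The stationary wavelet transform skips the downsampling of the decimated
DWT, so each level's output keeps the input's length and the transform is
shift-invariant.  One analysis step at level j pairs each sample with its
neighbour at stride 2^(j-1) under circular (periodic) indexing:

    approximation[i] = (x[i] + x[(i + s) mod N]) / sqrt(2)
    detail[i]        = (x[i] - x[(i + s) mod N]) / sqrt(2)

with the orthonormal Haar filter pair (1/sqrt(2), +-1/sqrt(2)).  The
feature vector of a sequence is the level-L approximation of its encoded
series, real channel followed by imaginary channel; detail coefficients
(local/noise structure) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complex_encoding import EncodedSeries

__all__ = [
    "HAAR_LOW",
    "HAAR_HIGH",
    "FeatureVector",
    "swt_level",
    "haar_swt_approx",
    "haar_sdwt_ac",
    "default_level",
]

_SQRT2 = np.sqrt(2.0)

# Orthonormal Haar analysis filters (unit L2 norm, mutually orthogonal).
HAAR_LOW: tuple[float, float] = (1.0 / _SQRT2, 1.0 / _SQRT2)
HAAR_HIGH: tuple[float, float] = (1.0 / _SQRT2, -1.0 / _SQRT2)


@dataclass(frozen=True)
class FeatureVector:
    """Level-L approximation coefficients of one sequence's encoded series.

    ``values`` has length Vec = 2 * |Sigma|^k: the real channel's level-L
    approximation followed by the imaginary channel's.
    """

    id: str
    values: np.ndarray
    level: int

    def __len__(self) -> int:
        return len(self.values)


def swt_level(signal: np.ndarray, level: int) -> tuple[np.ndarray, np.ndarray]:
    """One a-trous Haar analysis step at ``level`` with periodic extension.

    Stride is 2^(level-1); output length equals input length.  N must be
    divisible by 2^level (periodic SWT requirement).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if level < 1:
        raise ValueError("level must be a positive integer")
    n = len(signal)
    if n % (1 << level) != 0:
        raise ValueError(
            f"signal length {n} is not divisible by 2^{level}; "
            "the periodic stationary transform requires it"
        )
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    stride = 1 << (level - 1)
    neighbour = np.roll(signal, -stride)
    approx = (signal + neighbour) / _SQRT2
    detail = (signal - neighbour) / _SQRT2
    return approx, detail


def haar_swt_approx(signal: np.ndarray, level: int) -> np.ndarray:
    """Cascade ``swt_level`` for j = 1..level, keeping only approximations."""
    out = np.asarray(signal, dtype=float)
    for j in range(1, level + 1):
        out, _ = swt_level(out, j)
    return out


def haar_sdwt_ac(series: EncodedSeries, level: int) -> FeatureVector:
    """Level-``level`` stationary Haar feature vector of an encoded series.

    The real and imaginary channels are transformed independently and their
    level-L approximations concatenated (real block first), giving a vector
    of length 2 * |Sigma|^k.
    """
    n = len(series)
    if level < 1:
        raise ValueError("level must be a positive integer")
    if n % (1 << level) != 0:
        raise ValueError(
            f"series length {n} is not divisible by 2^{level}; "
            "use a smaller decomposition level"
        )
    values = np.concatenate(
        [haar_swt_approx(series.real, level), haar_swt_approx(series.imag, level)]
    )
    return FeatureVector(series.id, values, level)


def default_level(k: int) -> int:
    """Default decomposition level: L = k (empirically the most suitable)."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    return k
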