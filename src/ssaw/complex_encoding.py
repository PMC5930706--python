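"""Unit-circle complex encoding of standardized k-mer profiles.

The |Sigma|^k k-mer slots are spread evenly around the unit circle,
counterclockwise, in lexicographic order; slot t (1-based) sits at
phi_t = 360/|Sigma|^k * t degrees.  The point for a slot is
(sin phi_t, cos phi_t) — sine is the REAL part and cosine the IMAGINARY
part, deliberately the transpose of the usual convention.  A sequence's
encoded series multiplies each slot's point by its standardized frequency
S_t, giving a fixed-length series of complex pairs independent of sequence
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer_features import KmerIndex

__all__ = ["UnitCirclePlacement", "EncodedSeries", "place_on_circle", "encode"]


@dataclass(frozen=True)
class UnitCirclePlacement:
    """Angles (degrees) and unit-circle points for every k-mer slot."""

    index: KmerIndex
    angles_deg: np.ndarray  # shape (n_slots,)
    real: np.ndarray        # sin(phi), shape (n_slots,)
    imag: np.ndarray        # cos(phi), shape (n_slots,)

    @property
    def points(self) -> np.ndarray:
        """(n_slots, 2) array of (Real_t, Imag_t) pairs."""
        return np.column_stack([self.real, self.imag])


@dataclass(frozen=True)
class EncodedSeries:
    """CODE_S: the frequency-weighted complex series of one sequence.

    ``real``/``imag`` have one entry per k-mer slot, in lexicographic slot
    order; slot t holds S_t * (sin phi_t, cos phi_t).
    """

    id: str
    real: np.ndarray
    imag: np.ndarray

    def __len__(self) -> int:
        return len(self.real)

    @property
    def pairs(self) -> np.ndarray:
        return np.column_stack([self.real, self.imag])


def place_on_circle(index: KmerIndex) -> UnitCirclePlacement:
    """Distribute the k-mer slots evenly around the unit circle.

    t is 1-based: the alphabetically first k-mer gets the smallest positive
    angle (22.5 degrees for DNA k=2), and the last slot lands on a full
    turn.  Trigonometry is evaluated after degree-to-radian conversion.
    """
    n = len(index)
    t = np.arange(1, n + 1, dtype=float)
    angles = 360.0 / n * t
    rad = np.deg2rad(angles)
    return UnitCirclePlacement(index, angles, np.sin(rad), np.cos(rad))


def encode(
    scores: np.ndarray,
    placement: UnitCirclePlacement,
    sequence_id: str = "",
) -> EncodedSeries:
    """Weight each slot's circle point by the standardized frequency S_t."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != placement.real.shape:
        raise ValueError(
            f"score vector length {scores.shape} does not match the "
            f"{len(placement.real)} k-mer slots"
        )
    return EncodedSeries(sequence_id, scores * placement.real, scores * placement.imag)
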