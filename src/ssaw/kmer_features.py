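"""k-mer extraction, counting and collection-wide z-score standardization.

A length-M sequence yields M-k+1 overlapping windows; counts are tallied
into the |Sigma|^k lexicographically sorted k-mer slots.  Each slot is then
standardized across the collection: S_t = (X_t - mean) / sd, so that a
sequence's profile records how its k-mer usage deviates from the collection
norm rather than its raw composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .seq_io import Alphabet, SequenceCollection, SequenceRecord

__all__ = [
    "KmerIndex",
    "KmerFrequencyTable",
    "recommend_k",
    "count_kmers",
    "count_matrix",
    "standardize",
    "apply_standardization",
    "frequency_matrix",
]


class KmerIndex:
    """All |Sigma|^k k-mers of an alphabet in strict lexicographic order.

    ``rank`` is 1-based: the alphabetically first k-mer (A...A) has t = 1.
    """

    def __init__(self, k: int, alphabet: Alphabet) -> None:
        if k < 1:
            raise ValueError("k must be a positive integer")
        self.k = k
        self.alphabet = alphabet
        self.slots: tuple[str, ...] = tuple(
            "".join(p) for p in product(alphabet.symbols, repeat=k)
        )
        self._rank = {kmer: t for t, kmer in enumerate(self.slots, start=1)}

    def __len__(self) -> int:
        return len(self.slots)

    def rank(self, kmer: str) -> int:
        return self._rank[kmer]

    def __repr__(self) -> str:  # pragma: no cover
        return f"KmerIndex(k={self.k}, alphabet={self.alphabet.name}, slots={len(self)})"


@dataclass
class KmerFrequencyTable:
    """Raw counts and standardized scores for a collection.

    ``X`` is the (n_sequences, n_slots) integer count matrix, ``mean`` and
    ``sd`` the per-slot statistics over the collection, ``S`` the z-scores.
    Slots whose sd is zero carry S = 0 for every sequence (the slot is
    uninformative; zeroing avoids a 0/0).
    """

    index: KmerIndex
    ids: list[str]
    X: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    S: np.ndarray


def recommend_k(collection: SequenceCollection) -> int:
    """Recommended window length: ceil(log_|Sigma|(mean length) / 2), >= 1.

    Equivalently ceil(log_|Sigma| sqrt(mean length)): the k at which the
    number of k-mer slots roughly matches the square root of the typical
    sequence length.
    """
    if len(collection) == 0:
        raise ValueError("cannot recommend k for an empty collection")
    mean_len = collection.mean_length()
    k = math.ceil(math.log(mean_len, collection.alphabet.size) / 2)
    return max(k, 1)


def count_kmers(
    record: SequenceRecord,
    index: KmerIndex,
    drop_ambiguous: bool = False,
) -> np.ndarray:
    """Count every overlapping window of length k in one sequence.

    Returns an integer vector over the |Sigma|^k slots summing to M-k+1.
    With ``drop_ambiguous`` windows containing out-of-alphabet symbols are
    skipped instead of raising.
    """
    k = index.k
    if record.length < k:
        raise ValueError(
            f"record {record.id!r} (length {record.length}) is shorter than k={k}"
        )
    counts = np.zeros(len(index), dtype=np.int64)
    residues = record.residues
    for i in range(record.length - k + 1):
        window = residues[i : i + k]
        try:
            counts[index.rank(window) - 1] += 1
        except KeyError:
            if not drop_ambiguous:
                raise ValueError(
                    f"record {record.id!r} contains k-mer {window!r} outside "
                    f"the {index.alphabet.name} alphabet"
                ) from None
    return counts


def count_matrix(
    collection: SequenceCollection,
    index: KmerIndex,
    drop_ambiguous: bool = False,
) -> np.ndarray:
    """Stack per-record count vectors into an (n, |Sigma|^k) matrix."""
    return np.stack(
        [count_kmers(r, index, drop_ambiguous=drop_ambiguous) for r in collection]
    )


def standardize(
    counts: np.ndarray,
    index: KmerIndex,
    ids: Sequence[str],
    ddof: int = 1,
) -> KmerFrequencyTable:
    """z-score each k-mer slot across the sequences of a collection.

    ``ddof=1`` (sample standard deviation) is the default convention;
    pass ``ddof=0`` for the population form.  Requires at least two
    sequences — a single sequence has no collection to standardize against.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != len(index):
        raise ValueError("counts must be (n_sequences, n_slots)")
    if counts.shape[0] < 2:
        raise ValueError(
            "standardization needs a collection of at least 2 sequences "
            "(per-slot sd is undefined for one)"
        )
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=ddof)
    S = apply_standardization(counts, mean, sd)
    return KmerFrequencyTable(index, list(ids), counts, mean, sd, S)


def apply_standardization(counts: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """S = (X - mean)/sd with zero-sd slots mapped to 0.

    Used both for a collection's own statistics and to encode new sequences
    against a reference collection's frozen mean/sd.
    """
    counts = np.asarray(counts, dtype=float)
    sd = np.asarray(sd, dtype=float)
    safe = np.where(sd > 0, sd, 1.0)
    S = np.where(sd > 0, (counts - mean) / safe, 0.0)
    return S if S.ndim else S[()]


def frequency_matrix(table: KmerFrequencyTable) -> np.ndarray:
    """The (sequences x slots) matrix of standardized scores S_t.

    Rows follow collection order, columns lexicographic slot order.
    """
    return table.S
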