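"""End-to-end feature pipeline: counts -> z-scores -> circle -> SWT.

`SSAWEncoder` follows the fit/transform idiom: ``fit`` learns the per-slot
count mean and standard deviation from a reference collection, ``transform``
encodes any collection against those frozen statistics.  Freezing prevents
information leaking from test sequences into the feature space when
classifying new data against a trained set.
"""

from __future__ import annotations

import numpy as np

from .complex_encoding import encode, place_on_circle
from .kmer_features import (
    KmerIndex,
    apply_standardization,
    count_matrix,
    recommend_k,
    standardize,
)
from .seq_io import SequenceCollection
from .swt import default_level, haar_sdwt_ac

__all__ = ["SSAWEncoder", "feature_matrix"]


class SSAWEncoder:
    """Turn sequences into fixed-length stationary-wavelet feature vectors.

    Parameters
    ----------
    k : int or None
        k-mer window length; ``None`` resolves via the recommendation
        ceil(log_|Sigma|(mean length)/2) on the fitted collection.
    level : int or None
        SWT decomposition level; ``None`` resolves to L = k.
    ddof : int
        Delta degrees of freedom of the per-slot standard deviation
        (1 = sample convention, the default).
    """

    def __init__(self, k: int | None = None, level: int | None = None, ddof: int = 1) -> None:
        self.k = k
        self.level = level
        self.ddof = ddof
        self.index_: KmerIndex | None = None
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, collection: SequenceCollection) -> "SSAWEncoder":
        """Learn slot statistics (mean, sd per k-mer) from ``collection``."""
        k = self.k if self.k is not None else recommend_k(collection)
        self.resolved_k_ = k
        self.resolved_level_ = self.level if self.level is not None else default_level(k)
        self.index_ = KmerIndex(k, collection.alphabet)
        counts = count_matrix(collection, self.index_)
        table = standardize(counts, self.index_, collection.ids, ddof=self.ddof)
        self.mean_ = table.mean
        self.sd_ = table.sd
        self.placement_ = place_on_circle(self.index_)
        return self

    def transform(self, collection: SequenceCollection) -> tuple[list[str], np.ndarray]:
        """Encode a collection against the fitted statistics.

        Returns (ids, matrix) with one length-2*|Sigma|^k feature vector per
        row, in collection order.
        """
        if self.index_ is None:
            raise RuntimeError("encoder is not fitted; call fit() first")
        counts = count_matrix(collection, self.index_)
        scores = apply_standardization(counts, self.mean_, self.sd_)
        rows = [
            haar_sdwt_ac(encode(s, self.placement_, rid), self.resolved_level_).values
            for rid, s in zip(collection.ids, scores)
        ]
        return collection.ids, np.stack(rows)

    def fit_transform(self, collection: SequenceCollection) -> tuple[list[str], np.ndarray]:
        return self.fit(collection).transform(collection)


def feature_matrix(
    collection: SequenceCollection,
    k: int | None = None,
    level: int | None = None,
    ddof: int = 1,
) -> tuple[list[str], np.ndarray, SSAWEncoder]:
    """Fit-and-transform convenience: (ids, features, fitted encoder)."""
    enc = SSAWEncoder(k=k, level=level, ddof=ddof)
    ids, X = enc.fit_transform(collection)
    return ids, X, enc
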