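"""Distances, clustering/classification evaluation, and validity oracles.

Feature vectors are compared by Euclidean distance.  Clustering quality is
scored with the dominating-rule F-score: each cluster is assigned the family
contributing most of its members, and per-family precision/recall/F are
aggregated weighted by family size.  Classification uses 1-nearest-neighbour
with confusion-matrix metrics.  Edit distance, Needleman-Wunsch global
alignment identity and Pearson correlation serve as independent validity
oracles for the alignment-free distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import pearsonr
from sklearn.cluster import KMeans

from .pipeline import SSAWEncoder
from .seq_io import SequenceCollection

__all__ = [
    "euclidean",
    "DistanceMatrix",
    "pairwise_distance_matrix",
    "kmeans_cluster",
    "ClusteringContingency",
    "ClusteringScores",
    "clustering_fscore",
    "clustering_experiment",
    "knn1_classify",
    "ConfusionMatrix",
    "classification_metrics",
    "stratified_split",
    "classification_experiment",
    "edit_distance",
    "nw_identity",
    "pearson",
    "validity_check",
    "ValidityReport",
]


# ---------------------------------------------------------------------------
# Distances


def euclidean(u: np.ndarray, v: np.ndarray) -> float:
    """L2 distance between two equal-length feature vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"feature vectors differ in length: {u.shape} vs {v.shape}")
    return float(np.sqrt(np.sum((u - v) ** 2)))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


def pairwise_distance_matrix(ids: Sequence[str], X: np.ndarray) -> DistanceMatrix:
    return DistanceMatrix(list(ids), squareform(pdist(np.asarray(X, dtype=float))))


# ---------------------------------------------------------------------------
# k-means clustering and the dominating-rule F-score


def kmeans_cluster(
    X: np.ndarray,
    n_clusters: int,
    restarts: int = 200,
    seed: int = 0,
) -> list[np.ndarray]:
    """Lloyd's k-means, one random data-point initialization per restart.

    Returns the assignment vector of every restart so downstream scores can
    be averaged across initializations.  Per-restart seeds are derived from
    the master ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if n_clusters < 1:
        raise ValueError("n_clusters must be at least 1")
    if n_clusters > len(X):
        raise ValueError("n_clusters exceeds the number of vectors")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(restarts):
        km = KMeans(
            n_clusters=n_clusters,
            init="random",
            n_init=1,
            max_iter=300,
            tol=1e-4,
            algorithm="lloyd",
            random_state=int(rng.integers(2**31)),
        )
        assignments.append(km.fit_predict(X))
    return assignments


class ClusteringContingency:
    """Family-by-cluster count table feeding the dominating-rule scores."""

    def __init__(self, counts: np.ndarray, families: Sequence[str] | None = None) -> None:
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.size == 0 or counts.sum() == 0:
            raise ValueError("contingency must be a non-empty 2-D count table")
        if (counts < 0).any():
            raise ValueError("contingency counts must be nonnegative")
        self.counts = counts
        self.families = (
            list(families) if families is not None else [str(i) for i in range(counts.shape[0])]
        )

    @classmethod
    def from_labels(
        cls, families: Sequence[str], clusters: Sequence[int]
    ) -> "ClusteringContingency":
        if len(families) != len(clusters):
            raise ValueError("families and clusters must have equal length")
        fam_levels = sorted(set(families))
        clu_levels = sorted(set(clusters))
        fidx = {f: i for i, f in enumerate(fam_levels)}
        cidx = {c: j for j, c in enumerate(clu_levels)}
        counts = np.zeros((len(fam_levels), len(clu_levels)), dtype=np.int64)
        for f, c in zip(families, clusters):
            counts[fidx[f], cidx[c]] += 1
        return cls(counts, fam_levels)

    @property
    def family_sizes(self) -> np.ndarray:  # C_i
        return self.counts.sum(axis=1)

    @property
    def cluster_sizes(self) -> np.ndarray:  # C-bar_j
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:  # C
        return int(self.counts.sum())

    def dominating_labels(self) -> np.ndarray:
        """lb(j) = argmax_i C_ij; ties go to the lowest family index."""
        return self.counts.argmax(axis=0)


@dataclass(frozen=True)
class ClusteringScores:
    fscore: float
    precision: float
    recall: float
    per_family: dict[str, tuple[float, float, float]]  # family -> (P, R, F)


def clustering_fscore(contingency: ClusteringContingency) -> ClusteringScores:
    """Dominating-rule precision/recall/F per family and size-weighted overall.

    Each cluster j is labelled with the family lb(j) that dominates it.  For
    family i, precision pools the clusters labelled i
    (sum C_ij / sum cluster sizes), recall divides the same numerator by the
    family size C_i.  A family never chosen as any cluster's label scores 0
    on all three (the pooled sums are empty; 0/0 := 0).  Overall scores are
    weighted by C_i / C.
    """
    counts = contingency.counts
    lb = contingency.dominating_labels()
    fam_sizes = contingency.family_sizes
    clu_sizes = contingency.cluster_sizes
    total = contingency.total

    per_family: dict[str, tuple[float, float, float]] = {}
    overall = np.zeros(3)
    for i, fam in enumerate(contingency.families):
        mask = lb == i
        hit = counts[i, mask].sum()
        pooled = clu_sizes[mask].sum()
        precision = hit / pooled if pooled > 0 else 0.0
        recall = hit / fam_sizes[i] if fam_sizes[i] > 0 else 0.0
        f = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        per_family[fam] = (precision, recall, f)
        overall += fam_sizes[i] / total * np.array([precision, recall, f])
    return ClusteringScores(
        fscore=float(overall[2]),
        precision=float(overall[0]),
        recall=float(overall[1]),
        per_family=per_family,
    )


def clustering_experiment(
    X: np.ndarray,
    families: Sequence[str],
    n_clusters: int | None = None,
    restarts: int = 200,
    seed: int = 0,
    best_of: bool = False,
) -> tuple[ClusteringScores, list[ClusteringScores]]:
    """Repeated randomly-initialized k-means scored with the dominating rule.

    ``n_clusters`` defaults to the number of distinct families.  Returns the
    summary (mean across restarts, or the best restart with ``best_of``) and
    every restart's scores.
    """
    if n_clusters is None:
        n_clusters = len(set(families))
    per_restart = [
        clustering_fscore(ClusteringContingency.from_labels(families, assign))
        for assign in kmeans_cluster(X, n_clusters, restarts=restarts, seed=seed)
    ]
    if best_of:
        summary = max(per_restart, key=lambda s: s.fscore)
    else:
        summary = ClusteringScores(
            fscore=float(np.mean([s.fscore for s in per_restart])),
            precision=float(np.mean([s.precision for s in per_restart])),
            recall=float(np.mean([s.recall for s in per_restart])),
            per_family={},
        )
    return summary, per_restart


# ---------------------------------------------------------------------------
# 1-NN classification and confusion-matrix metrics


def knn1_classify(
    train_X: np.ndarray,
    train_labels: Sequence[str],
    test_X: np.ndarray,
) -> list[str]:
    """Label each test vector by its Euclidean-nearest training vector.

    Distance ties resolve to the earliest training index (argmin order).
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    if len(train_X) == 0:
        raise ValueError("training set is empty")
    if len(train_labels) != len(train_X):
        raise ValueError("every training vector needs a label")
    nearest = cdist(test_X, train_X).argmin(axis=1)
    labels = list(train_labels)
    return [labels[i] for i in nearest]


class ConfusionMatrix:
    """Predicted-vs-actual counts with one-vs-rest per-class breakdowns."""

    def __init__(self, actual: Sequence[str], predicted: Sequence[str]) -> None:
        if len(actual) != len(predicted):
            raise ValueError("actual and predicted must have equal length")
        if len(actual) == 0:
            raise ValueError("no predictions to score")
        self.classes = sorted(set(actual) | set(predicted))
        idx = {c: i for i, c in enumerate(self.classes)}
        n = len(self.classes)
        self.table = np.zeros((n, n), dtype=np.int64)  # rows actual, cols predicted
        for a, p in zip(actual, predicted):
            self.table[idx[a], idx[p]] += 1
        self.total = len(actual)

    def counts(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) treating ``cls`` as the positive class."""
        i = self.classes.index(cls)
        tp = int(self.table[i, i])
        fp = int(self.table[:, i].sum() - tp)
        fn = int(self.table[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def class_metrics(self, cls: str) -> tuple[float, float, float, float]:
        """(accuracy, precision, recall, F) for one positive class.

        Accuracy = (TP+TN)/total; precision = TP/(TP+FP);
        recall = TP/(TP+FN); F = harmonic mean.  Empty denominators give 0.
        """
        tp, fp, fn, tn = self.counts(cls)
        accuracy = (tp + tn) / self.total
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        return accuracy, precision, recall, f


def classification_metrics(
    actual: Sequence[str], predicted: Sequence[str]
) -> tuple[float, float, float, float]:
    """(accuracy, F-score, precision, recall) over all classes.

    Accuracy is micro (fraction correct); precision, recall and F are
    macro-averaged over the one-vs-rest per-class values.
    """
    cm = ConfusionMatrix(actual, predicted)
    accuracy = float(np.trace(cm.table)) / cm.total
    per = np.array([cm.class_metrics(c)[1:] for c in cm.classes])  # (P, R, F)
    precision, recall, fscore = per.mean(axis=0)
    return accuracy, float(fscore), float(precision), float(recall)


def stratified_split(
    labels: dict[str, str],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Per-class split: ceil(fraction * n) ids to train, at least 1 to test.

    Sampling is without replacement under ``seed``; train and test partition
    the labelled ids.  A class with a single member cannot be split.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    by_class: dict[str, list[str]] = {}
    for rid, lab in labels.items():
        by_class.setdefault(lab, []).append(rid)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for lab in sorted(by_class):
        members = sorted(by_class[lab])
        if len(members) < 2:
            raise ValueError(f"class {lab!r} has a single member and cannot be split")
        n_train = min(int(np.ceil(train_fraction * len(members))), len(members) - 1)
        perm = rng.permutation(len(members))
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return train, test


def classification_experiment(
    collection: SequenceCollection,
    k: int | None = None,
    level: int | None = None,
    repeats: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[tuple[float, float, float, float], list[tuple[float, float, float, float]]]:
    """Repeated stratified-split 1-NN evaluation on SSAW features.

    Each repeat fits the encoder (k-mer statistics) on the training subset
    only, transforms both subsets against those frozen statistics, classifies
    the held-out 20 percent, and scores it.  Returns the mean
    (accuracy, F, precision, recall) and every repeat's tuple.
    """
    if not collection.labels:
        raise ValueError("classification requires labelled sequences")
    rng = np.random.default_rng(seed)
    per_repeat = []
    for _ in range(repeats):
        split_seed = int(rng.integers(2**31))
        train_ids, test_ids = stratified_split(
            collection.labels, train_fraction, seed=split_seed
        )
        train_coll = collection.subset(train_ids)
        test_coll = collection.subset(test_ids)
        enc = SSAWEncoder(k=k, level=level).fit(train_coll)
        _, train_X = enc.transform(train_coll)
        _, test_X = enc.transform(test_coll)
        predicted = knn1_classify(
            train_X, [collection.labels[i] for i in train_ids], test_X
        )
        actual = [collection.labels[i] for i in test_ids]
        per_repeat.append(classification_metrics(actual, predicted))
    mean = tuple(float(v) for v in np.mean(per_repeat, axis=0))
    return mean, per_repeat


# ---------------------------------------------------------------------------
# Validity oracles: edit distance, NW identity, Pearson correlation


def edit_distance(s: str, t: str) -> int:
    """Levenshtein distance (unit-cost substitution/insertion/deletion).

    Row-wise dynamic programme; the in-row dependency is resolved with a
    running-minimum pass so each row is vectorised.
    """
    if len(s) == 0 or len(t) == 0:
        return max(len(s), len(t))
    t_arr = np.frombuffer(t.encode("latin-1"), dtype=np.uint8)
    n = len(t)
    j_idx = np.arange(n + 1)
    prev = j_idx.copy()
    for i, ch in enumerate(s.encode("latin-1"), start=1):
        candidate = np.minimum(prev[1:] + 1, prev[:-1] + (t_arr != ch))
        row = np.concatenate(([i], candidate))
        # row[j] = min over m<=j of row[m] + (j - m)
        prev = np.minimum.accumulate(row - j_idx) + j_idx
    return int(prev[-1])


def _nw_matrix(s: str, t: str) -> np.ndarray:
    """Global-alignment score matrix under match=+1, mismatch=-1, gap=-1."""
    m, n = len(s), len(t)
    t_arr = np.frombuffer(t.encode("latin-1"), dtype=np.uint8)
    j_idx = np.arange(n + 1)
    H = np.empty((m + 1, n + 1), dtype=np.int64)
    H[0] = -j_idx
    for i, ch in enumerate(s.encode("latin-1"), start=1):
        sub = np.where(t_arr == ch, 1, -1)
        candidate = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] - 1)
        row = np.concatenate(([-i], candidate))
        # row[j] = max over m<=j of row[m] - (j - m): gap extension to the left
        H[i] = np.maximum.accumulate(row + j_idx) - j_idx
    return H


def nw_identity(s: str, t: str) -> float:
    """Identity of the optimal Needleman-Wunsch global alignment.

    Scoring is match=+1, mismatch=-1, gap=-1; identity is the fraction of
    aligned columns that are matches.  Traceback ties prefer diagonal, then
    a gap in the second sequence, then a gap in the first (deterministic).
    """
    if len(s) == 0 or len(t) == 0:
        raise ValueError("global alignment identity requires non-empty strings")
    H = _nw_matrix(s, t)
    i, j = len(s), len(t)
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = 1 if s[i - 1] == t[j - 1] else -1
            if H[i, j] == H[i - 1, j - 1] + sub:
                matches += s[i - 1] == t[j - 1]
                i, j = i - 1, j - 1
                columns += 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("pearson needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson is undefined for a constant vector")
    return float(pearsonr(x, y).statistic)


@dataclass(frozen=True)
class ValidityReport:
    """Correlation of SSAW distances with the alignment-based oracles."""

    n_sequences: int
    n_pairs: int
    r_edit: float
    r_identity: float


def validity_check(
    collection: SequenceCollection,
    k: int | None = None,
    level: int | None = None,
    max_sequences: int = 100,
    seed: int = 0,
) -> ValidityReport:
    """Correlate SSAW distances with edit distance and NW identity.

    At most ``max_sequences`` records are sampled (seeded, without
    replacement); all pairwise SSAW Euclidean distances, Levenshtein
    distances and alignment identities are computed over the sample and the
    two Pearson correlations returned.  A distance measure should correlate
    positively with edit distance and negatively with identity.
    """
    if len(collection) < 3:
        raise ValueError("validity check needs at least 3 sequences")
    ids = collection.ids
    if len(ids) > max_sequences:
        rng = np.random.default_rng(seed)
        ids = [ids[i] for i in sorted(rng.choice(len(ids), max_sequences, replace=False))]
    sub = collection.subset(ids)
    enc = SSAWEncoder(k=k, level=level).fit(sub)
    _, X = enc.transform(sub)
    ssaw_d = pdist(X)
    seqs = [sub[i].residues for i in ids]
    edits = []
    idents = []
    for a in range(len(seqs)):
        for b in range(a + 1, len(seqs)):
            edits.append(edit_distance(seqs[a], seqs[b]))
            idents.append(nw_identity(seqs[a], seqs[b]))
    return ValidityReport(
        n_sequences=len(ids),
        n_pairs=len(edits),
        r_edit=pearson(ssaw_d, edits),
        r_identity=pearson(ssaw_d, idents),
    )
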