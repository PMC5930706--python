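from functools import lru_cache

import edlib
import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.metrics import precision_recall_fscore_support

from ssaw.metrics_eval import (
    ClusteringContingency,
    ConfusionMatrix,
    classification_metrics,
    clustering_fscore,
    edit_distance,
    euclidean,
    kmeans_cluster,
    knn1_classify,
    nw_identity,
    pairwise_distance_matrix,
    pearson,
    stratified_split,
    validity_check,
)
from ssaw.seq_io import DNA, SequenceCollection, SequenceRecord

vectors = hnp.arrays(float, 8, elements=st.floats(-50, 50, allow_nan=False, width=32))
short_dna = st.text(alphabet="ACGT", min_size=0, max_size=7)


class TestEuclidean:
    def test_identity_and_345(self):
        assert euclidean([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert euclidean([0.0, 0.0], [3.0, 4.0]) == 5.0

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            euclidean([1.0], [1.0, 2.0])

    @given(u=vectors, v=vectors, w=vectors)
    def test_metric_axioms(self, u, v, w):
        assert euclidean(u, v) >= 0
        assert euclidean(u, v) == pytest.approx(euclidean(v, u))
        assert euclidean(u, w) <= euclidean(u, v) + euclidean(v, w) + 1e-9

    def test_distance_matrix_is_symmetric_zero_diagonal(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        dm = pairwise_distance_matrix([f"s{i}" for i in range(5)], X)
        assert np.allclose(dm.d, dm.d.T, atol=1e-12)
        assert np.all(np.diag(dm.d) == 0)


class TestKmeans:
    def test_separated_clouds_recovered_every_restart(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(100, 1, (10, 2))])
        planted = np.array([0] * 10 + [1] * 10)
        for assign in kmeans_cluster(X, 2, restarts=20, seed=5):
            same = (assign == planted).all() or (assign == 1 - planted).all()
            assert same

    def test_each_point_its_own_cluster(self):
        X = np.arange(8.0).reshape(4, 2)
        for assign in kmeans_cluster(X, 4, restarts=3, seed=0):
            assert len(set(assign)) == 4

    def test_invalid_n_clusters(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 2)), 0)
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 2)), 4)


class TestClusteringFscore:
    def test_perfect_clustering_scores_one(self):
        scores = clustering_fscore(ClusteringContingency(np.diag([5, 7, 3])))
        assert scores.fscore == scores.precision == scores.recall == 1.0

    def test_hand_derived_2x2_table(self):
        scores = clustering_fscore(
            ClusteringContingency(np.array([[3, 1], [0, 4]]), ["f1", "f2"])
        )
        p1, r1, f1 = scores.per_family["f1"]
        p2, r2, f2 = scores.per_family["f2"]
        assert (p1, r1) == (1.0, 0.75) and round(f1, 4) == 0.8571
        assert (p2, r2) == (0.8, 1.0) and round(f2, 4) == 0.8889
        assert round(scores.fscore, 4) == 0.8730

    def test_single_cluster_tie_goes_to_lowest_family(self):
        # two equal families collapsed into one cluster: lb = first family
        scores = clustering_fscore(
            ClusteringContingency(np.array([[4], [4]]), ["a", "b"])
        )
        pa, ra, fa = scores.per_family["a"]
        assert (pa, ra) == (0.5, 1.0)
        assert scores.per_family["b"] == (0.0, 0.0, 0.0)
        assert scores.fscore == pytest.approx(0.5 * fa)

    def test_scores_bounded_and_one_iff_pure(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.integers(0, 9, size=(3, 4))
            if counts.sum() == 0:
                continue
            s = clustering_fscore(ClusteringContingency(counts))
            assert 0.0 <= s.fscore <= 1.0

    def test_empty_contingency_errors(self):
        with pytest.raises(ValueError):
            ClusteringContingency(np.zeros((2, 2), dtype=int))


class TestKnn1:
    def test_single_training_point_labels_everything(self):
        assert knn1_classify([[0.0, 0.0]], ["a"], [[5.0, 5.0], [-1.0, 0.0]]) == ["a", "a"]

    def test_coincident_point_wins(self):
        pred = knn1_classify([[0.0], [3.0]], ["a", "b"], [[3.0]])
        assert pred == ["b"]

    def test_nearer_point_wins_and_ties_go_first(self):
        assert knn1_classify([[0.0], [10.0]], ["a", "b"], [[2.0]]) == ["a"]
        assert knn1_classify([[0.0], [2.0]], ["a", "b"], [[1.0]]) == ["a"]

    def test_unlabelled_training_errors(self):
        with pytest.raises(ValueError):
            knn1_classify([[0.0], [1.0]], ["a"], [[0.5]])


def binary_labels(tp, fp, fn, tn):
    actual = ["pos"] * (tp + fn) + ["neg"] * (fp + tn)
    predicted = ["pos"] * tp + ["neg"] * fn + ["pos"] * fp + ["neg"] * tn
    return actual, predicted


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        labels = ["a", "b", "c", "a"]
        assert classification_metrics(labels, labels) == (1.0, 1.0, 1.0, 1.0)

    def test_printed_formulas_on_binary_counts(self):
        actual, predicted = binary_labels(tp=3, fp=1, fn=2, tn=4)
        cm = ConfusionMatrix(actual, predicted)
        assert cm.counts("pos") == (3, 1, 2, 4)
        accuracy, precision, recall, f = cm.class_metrics("pos")
        assert accuracy == pytest.approx(0.7)
        assert precision == pytest.approx(0.75)
        assert recall == pytest.approx(0.6)
        assert round(f, 4) == 0.6667

    def test_all_wrong_binary(self):
        actual = ["pos", "neg"]
        predicted = ["neg", "pos"]
        accuracy, f, precision, recall = classification_metrics(actual, predicted)
        assert accuracy == f == precision == recall == 0.0

    def test_macro_average_matches_sklearn(self):
        rng = np.random.default_rng(2)
        classes = ["a", "b", "c"]
        actual = [classes[i] for i in rng.integers(0, 3, 60)]
        predicted = [classes[i] for i in rng.integers(0, 3, 60)]
        _, f, p, r = classification_metrics(actual, predicted)
        sp, sr, sf, _ = precision_recall_fscore_support(
            actual, predicted, average="macro", zero_division=0
        )
        assert (p, r, f) == (pytest.approx(sp), pytest.approx(sr), pytest.approx(sf))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            classification_metrics(["a"], ["a", "b"])


class TestStratifiedSplit:
    def test_single_class_80_20(self):
        labels = {f"s{i}": "fam" for i in range(10)}
        train, test = stratified_split(labels, 0.8, seed=1)
        assert len(train) == 8 and len(test) == 2
        assert set(train) | set(test) == set(labels) and not set(train) & set(test)

    def test_two_balanced_classes(self):
        labels = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)}
        train, test = stratified_split(labels, 0.8, seed=1)
        assert len(train) == 8 and len(test) == 2
        assert {l for i, l in labels.items() if i in test} == {"A", "B"}

    def test_same_seed_reproduces_split(self):
        labels = {f"s{i}": "AB"[i % 2] for i in range(20)}
        assert stratified_split(labels, 0.8, seed=7) == stratified_split(labels, 0.8, seed=7)

    def test_singleton_class_errors(self):
        with pytest.raises(ValueError, match="lonely"):
            stratified_split({"x": "lonely", "a": "fam", "b": "fam"}, 0.8, seed=0)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            stratified_split({"a": "f", "b": "f"}, 1.0, seed=0)


@lru_cache(maxsize=None)
def recursive_edit(s, t):
    """Textbook recursion, independent of the DP implementation."""
    if not s:
        return len(t)
    if not t:
        return len(s)
    return min(
        recursive_edit(s[1:], t[1:]) + (s[0] != t[0]),
        recursive_edit(s[1:], t) + 1,
        recursive_edit(s, t[1:]) + 1,
    )


class TestEditDistance:
    def test_known_values(self):
        assert edit_distance("ACGT", "ACGT") == 0
        assert edit_distance("", "ACG") == 3
        assert edit_distance("AACAA", "CCGCC") == 5
        assert recursive_edit("AACAA", "CCGCC") == 5

    @given(s=short_dna, t=short_dna)
    def test_matches_recursive_oracle(self, s, t):
        assert edit_distance(s, t) == recursive_edit(s, t)

    @given(s=short_dna, t=short_dna, u=short_dna)
    def test_triangle_inequality(self, s, t, u):
        assert edit_distance(s, u) <= edit_distance(s, t) + edit_distance(t, u)

    @settings(max_examples=25)
    @given(
        s=st.text(alphabet="ACGT", min_size=1, max_size=60),
        t=st.text(alphabet="ACGT", min_size=1, max_size=60),
    )
    def test_matches_edlib(self, s, t):
        assert edit_distance(s, t) == edlib.align(s, t, task="distance")["editDistance"]


def exhaustive_alignments(s, t):
    """Every global alignment's (score, matches, columns), by enumeration."""
    results = []

    def go(i, j, score, matches, columns):
        if i == len(s) and j == len(t):
            results.append((score, matches, columns))
            return
        if i < len(s) and j < len(t):
            m = s[i] == t[j]
            go(i + 1, j + 1, score + (1 if m else -1), matches + m, columns + 1)
        if i < len(s):
            go(i + 1, j, score - 1, matches, columns + 1)
        if j < len(t):
            go(i, j + 1, score - 1, matches, columns + 1)

    go(0, 0, 0, 0, 0)
    return results


class TestNwIdentity:
    def test_identical_strings(self):
        assert nw_identity("ACGTA", "ACGTA") == 1.0

    def test_disjoint_alphabets(self):
        assert nw_identity("AAAA", "CCCC") == 0.0

    def test_empty_string_errors(self):
        with pytest.raises(ValueError):
            nw_identity("", "ACG")

    def test_against_exhaustive_oracle(self):
        s, t = "AACAA", "CCGCC"
        alignments = exhaustive_alignments(s, t)
        best = max(a[0] for a in alignments)
        optimal_identities = {m / c for sc, m, c in alignments if sc == best}
        assert nw_identity(s, t) in optimal_identities

    @settings(max_examples=25)
    @given(
        s=st.text(alphabet="ACGT", min_size=1, max_size=25),
        t=st.text(alphabet="ACGT", min_size=1, max_size=25),
    )
    def test_score_matches_biopython(self, s, t):
        from ssaw.metrics_eval import _nw_matrix

        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=-1,
            extend_gap_score=-1,
        )
        assert _nw_matrix(s, t)[len(s), len(t)] == aligner.score(s, t)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))

    def test_independent_samples_weakly_correlated(self):
        rng = np.random.default_rng(11)
        assert abs(pearson(rng.normal(size=1000), rng.normal(size=1000))) < 0.2


class TestValidityCheck:
    def test_identical_sequences_error(self):
        coll = SequenceCollection(
            [SequenceRecord(f"s{i}", "ACGTACGTACGTACGT") for i in range(4)], DNA
        )
        with pytest.raises(ValueError):
            validity_check(coll, k=1, level=1)

    def test_two_sequences_error(self):
        coll = SequenceCollection(
            [SequenceRecord("a", "ACGTACGT"), SequenceRecord("b", "TTGTACGA")], DNA
        )
        with pytest.raises(ValueError):
            validity_check(coll, k=1, level=1)
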