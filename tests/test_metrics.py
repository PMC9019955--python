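"""Evaluation metrics against scikit-learn/scipy reference implementations."""

import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    normalized_mutual_info_score,
    precision_recall_fscore_support,
)

from anchorcell.metrics import (
    MetricError,
    ami,
    batch_mixing,
    entropy,
    mutual_information,
    nmi,
    pair_confusion,
    pearson,
    precision_recall_f1,
    rand_indices,
)


def random_partitions(rng, n_pairs=100, n_max=50):
    for _ in range(n_pairs):
        n = rng.integers(4, n_max + 1)
        yield (
            rng.integers(0, rng.integers(2, 6), n),
            rng.integers(0, rng.integers(2, 6), n),
        )


class TestNMI:
    def test_identical_partitions(self, rng):
        U = rng.integers(0, 3, 30)
        assert nmi(U, U) == pytest.approx(1.0)

    def test_constant_vs_informative_zero(self):
        assert nmi(np.zeros(10), np.arange(10) % 2) == 0.0

    def test_independent_blocks_zero(self):
        U = np.array([0, 0, 1, 1])
        V = np.array([0, 1, 0, 1])
        assert nmi(U, V) == pytest.approx(0.0, abs=1e-12)

    def test_single_class_both_one(self):
        assert nmi(np.zeros(5), np.ones(5)) == 1.0

    def test_matches_sklearn(self, rng):
        for U, V in random_partitions(rng):
            assert nmi(U, V) == pytest.approx(
                normalized_mutual_info_score(U, V), abs=1e-10
            )


class TestBatchMixing:
    def test_confounded_and_independent(self):
        batch = np.array([0, 0, 1, 1])
        assert batch_mixing(batch, batch) == pytest.approx(0.0)
        checker = np.array([0, 1, 0, 1])
        assert batch_mixing(checker, batch) == pytest.approx(1.0)


class TestAMI:
    def test_identical_is_one(self, rng):
        U = rng.integers(0, 4, 40)
        assert ami(U, U) == pytest.approx(1.0)

    def test_independent_labels_near_zero(self):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            vals.append(ami(r.integers(0, 5, 1000), r.integers(0, 5, 1000)))
        assert np.all(np.abs(vals) < 0.05)

    def test_chance_corrected_below_nmi(self, rng):
        for U, V in random_partitions(rng):
            assert ami(U, V) <= nmi(U, V) + 1e-10

    def test_matches_sklearn(self, rng):
        for U, V in random_partitions(rng, n_pairs=50):
            assert ami(U, V) == pytest.approx(
                adjusted_mutual_info_score(U, V), abs=1e-10
            )


class TestRandIndices:
    def test_hand_counts(self):
        # U=(0,0,0,1), V=(0,0,1,1): tp=1, pairs=6
        U = np.array([0, 0, 0, 1])
        V = np.array([0, 0, 1, 1])
        tp, fp, tn, fn = pair_confusion(U, V)
        assert (tp, fp, tn, fn) == (1.0, 2.0, 2.0, 1.0)
        ri, _ = rand_indices(U, V)
        assert ri == pytest.approx((tp + tn) / 6)

    def test_identical_ari_one(self, rng):
        U = rng.integers(0, 3, 20)
        assert rand_indices(U, U)[1] == pytest.approx(1.0)

    def test_single_class_vs_balanced_two_class(self):
        _, ari = rand_indices(np.zeros(4), np.array([0, 0, 1, 1]))
        assert ari == pytest.approx(0.0)

    def test_matches_sklearn(self, rng):
        for U, V in random_partitions(rng):
            assert rand_indices(U, V)[1] == pytest.approx(
                adjusted_rand_score(U, V), abs=1e-10
            )

    def test_pair_counts_total(self, rng):
        U = rng.integers(0, 3, 25)
        V = rng.integers(0, 4, 25)
        assert sum(pair_confusion(U, V)) == 25 * 24 / 2


class TestPearson:
    def test_exact_cases(self):
        u = np.array([1.0, 2.0, 3.0])
        assert pearson(u, u) == pytest.approx(1.0)
        assert pearson(u, -u) == pytest.approx(-1.0)
        assert pearson(u, 2 * u) == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            u = rng.standard_normal(15)
            v = rng.standard_normal(15)
            assert pearson(u, v) == pytest.approx(
                scipy.stats.pearsonr(u, v).statistic, abs=1e-10
            )

    def test_constant_vector_error(self):
        with pytest.raises(MetricError):
            pearson(np.ones(5), np.arange(5.0))


class TestPRF:
    def test_perfect_prediction(self):
        y = np.array(["a", "b", "a"])
        assert precision_recall_f1(y, y) == (1.0, 1.0, 1.0)

    def test_hand_counts_single_class(self):
        truth = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        p, r, f = precision_recall_f1(pred, truth)
        # symmetric confusion: every class at 0.8
        assert (p, r, f) == (pytest.approx(0.8),) * 3

    def test_degenerate_single_prediction(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.zeros(4, dtype=int)
        _, r, _ = precision_recall_f1(pred, truth)
        assert r == pytest.approx(0.5)

    def test_matches_sklearn_weighted(self, rng):
        for _ in range(20):
            truth = rng.integers(0, 4, 60)
            pred = rng.integers(0, 4, 60)
            p, r, f = precision_recall_f1(pred, truth)
            sp, sr, sf, _ = precision_recall_fscore_support(
                truth, pred, average="weighted", zero_division=0
            )
            assert (p, r, f) == (
                pytest.approx(sp, abs=1e-10),
                pytest.approx(sr, abs=1e-10),
                pytest.approx(sf, abs=1e-10),
            )


class TestInvariances:
    def test_symmetry_and_relabeling(self, rng):
        U = rng.integers(0, 3, 40)
        V = rng.integers(0, 4, 40)
        assert nmi(U, V) == pytest.approx(nmi(V, U), abs=1e-12)
        assert ami(U, V) == pytest.approx(ami(V, U), abs=1e-12)
        assert rand_indices(U, V) == pytest.approx(rand_indices(V, U), abs=1e-12)
        # renaming labels changes nothing
        remap = {0: 7, 1: 3, 2: 9}
        U2 = np.array([remap[u] for u in U])
        assert nmi(U2, V) == pytest.approx(nmi(U, V), abs=1e-12)

    def test_entropy_and_mi_basics(self):
        assert entropy(np.array([0, 0, 1, 1])) == pytest.approx(np.log(2))
        U = np.array([0, 0, 1, 1])
        assert mutual_information(U, U) == pytest.approx(np.log(2))
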