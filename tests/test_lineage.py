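"""Trajectory tree, root selection and pseudotime."""

import numpy as np
import pytest

from anchorcell.lineage import (
    LineageError,
    cluster_similarity_matrix,
    compute_pseudotime,
    infer_trajectory,
    select_root_cell,
)

from conftest import brute_force_best_tree


def double_loop_similarity(Z, labels):
    clusters = np.unique(labels)
    c = len(clusters)
    A = np.zeros((c, c))
    unit = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    for a, p in enumerate(clusters):
        for b, q in enumerate(clusters):
            rows_p = unit[labels == p]
            rows_q = unit[labels == q]
            total = sum(
                float(u @ v) for u in rows_p for v in rows_q
            )
            A[a, b] = total / (len(rows_p) * len(rows_q))
    return A


class TestClusterSimilarity:
    def test_singletons_are_pairwise_cosine(self):
        Z = np.array([[1.0, 0.0], [1.0, 1.0]])
        A = cluster_similarity_matrix(Z, np.array([0, 1]))
        assert A[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_identical_rows_self_similarity_one(self):
        Z = np.tile([0.3, 0.4], (4, 1))
        A = cluster_similarity_matrix(Z, np.zeros(4, dtype=int))
        assert A[0, 0] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        Z = rng.standard_normal((20, 4))
        labels = rng.integers(0, 3, 20)
        A = cluster_similarity_matrix(Z, labels)
        np.testing.assert_allclose(A, double_loop_similarity(Z, labels), atol=1e-10)


class TestInferTrajectory:
    def test_three_cluster_known_tree(self):
        A = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.8], [0.1, 0.8, 1.0]])
        tree = infer_trajectory(A, 0)
        assert tree.tree_edges == [(0, 1), (1, 2)]
        assert tree.parent[1] == 0 and tree.parent[2] == 1

    def test_two_clusters_trivial(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        tree = infer_trajectory(A, 1)
        assert tree.tree_edges == [(0, 1)]
        assert tree.root_cluster == 1

    @pytest.mark.parametrize("c", [4, 5, 6])
    def test_matches_brute_force_over_spanning_trees(self, rng, c):
        for _ in range(5):
            S = rng.random((c, c))
            A = (S + S.T) / 2
            np.fill_diagonal(A, 1.0)
            tree = infer_trajectory(A, 0)
            got = sum(A[u, v] for u, v in tree.tree_edges)
            best_w, _ = brute_force_best_tree(A)
            assert got == pytest.approx(best_w, abs=1e-10)

    def test_chain_structure_recovered_in_order(self):
        c = 5
        A = np.eye(c)
        for i in range(c - 1):
            A[i, i + 1] = A[i + 1, i] = 0.9
        for i in range(c):
            for j in range(i + 2, c):
                A[i, j] = A[j, i] = 0.1
        tree = infer_trajectory(A, 0)
        assert tree.tree_edges == [(i, i + 1) for i in range(c - 1)]
        # auto root should pick a chain endpoint (lowest-id tie break)
        assert infer_trajectory(A, "auto").root_cluster == 0

    def test_asymmetric_rejected(self):
        with pytest.raises(LineageError):
            infer_trajectory(np.array([[1.0, 0.2], [0.3, 1.0]]), 0)


class TestRootCellAndPseudotime:
    def _chain(self, rng, n_per=20, noise=0.05):
        # clusters at x = 0, 1, 2 on a line, small jitter
        Z, labels = [], []
        for c in range(3):
            pts = np.column_stack(
                [c + rng.uniform(0, 1, n_per), rng.normal(0, noise, n_per)]
            )
            Z.append(pts)
            labels += [c] * n_per
        return np.vstack(Z), np.array(labels)

    def test_singleton_root_cluster(self):
        Z = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        labels = np.array([0, 1, 2])
        tree = infer_trajectory(cluster_similarity_matrix(Z + 1, labels), 0)
        assert select_root_cell(Z, labels, tree) == 0

    def test_early_cell_selected_on_chain(self, rng):
        Z, labels = self._chain(rng)
        A = cluster_similarity_matrix(Z + np.array([1.0, 1.0]), labels)
        tree = infer_trajectory(A, 0)
        root = select_root_cell(Z, labels, tree)
        members = np.flatnonzero(labels == 0)
        # the accordance criterion trades distance to later clusters against
        # distances within the root cluster, so the winner sits in the
        # earlier half of the root cluster rather than at its very tip
        assert Z[root, 0] <= np.median(Z[members, 0])
        assert labels[root] == 0

    def test_identical_cells_tie_to_first_index(self):
        Z = np.ones((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        tree = infer_trajectory(np.array([[1.0, 1.0], [1.0, 1.0]]), 0)
        assert select_root_cell(Z, labels, tree) == 0

    def test_pseudotime_monotone_on_chain(self, rng):
        Z, labels = self._chain(rng)
        A = cluster_similarity_matrix(Z + np.array([2.0, 2.0]), labels)
        tree = infer_trajectory(A, 0)
        r1 = select_root_cell(Z, labels, tree)
        pt = compute_pseudotime(Z, labels, tree, r1)
        assert pt.D_norm.min() == 0.0 and pt.D_norm.max() == 1.0
        assert np.all(pt.D >= 0)
        # non-decreasing cluster-mean pseudotime along the lineage
        means = [pt.D_norm[labels == c].mean() for c in range(3)]
        assert means[0] < means[1] < means[2]
        # strong correlation with the latent coordinate
        r = np.corrcoef(pt.D_norm, Z[:, 0])[0, 1]
        assert r >= 0.9

    def test_root_cell_pseudotime_zero(self, rng):
        Z, labels = self._chain(rng)
        A = cluster_similarity_matrix(Z + np.array([2.0, 2.0]), labels)
        tree = infer_trajectory(A, 0)
        r1 = select_root_cell(Z, labels, tree)
        pt = compute_pseudotime(Z, labels, tree, r1)
        assert pt.D[r1] == pytest.approx(0.0)

    def test_coincident_cells_all_zero(self):
        Z = np.ones((4, 2))
        labels = np.array([0, 0, 1, 1])
        tree = infer_trajectory(np.ones((2, 2)), 0)
        with pytest.warns(UserWarning):
            pt = compute_pseudotime(Z, labels, tree, 0)
        assert np.all(pt.D_norm == 0)
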