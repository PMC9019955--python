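"""Bipartite graph construction and LAE simplex-constrained weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorcell.ghosts import GhostSet
from anchorcell.graph import (
    GraphError,
    build_sparse_encoding,
    cosine_similarity,
    lae_weights,
    project_simplex,
    select_nearest_ghosts,
)

from conftest import simplex_qp_oracle


def make_ghosts(U, m_h=None):
    U = np.asarray(U, dtype=float)
    if m_h is None:
        m_h = [U.shape[0]]
    offsets = list(np.cumsum([0] + m_h[:-1]))
    return GhostSet(U=U, m_h=m_h, batch_offsets=offsets, seed=0)


class TestCosine:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ((1, 0), (1, 0), 1.0),
            ((1, 0), (0, 1), 0.0),
            ((1, 1), (1, 0), 1 / np.sqrt(2)),
            ((0, 0), (1, 2), 0.0),  # zero-vector convention
        ],
    )
    def test_closed_forms(self, a, b, expect):
        assert cosine_similarity(np.array(a), np.array(b)) == pytest.approx(expect)

    def test_length_mismatch(self):
        with pytest.raises(GraphError):
            cosine_similarity(np.ones(2), np.ones(3))


class TestSelectNearestGhosts:
    def test_s_from_p(self, rng):
        ghosts = make_ghosts(rng.standard_normal((50, 3)), [50])
        _, s = select_nearest_ghosts(rng.standard_normal((5, 3)), ghosts, 0.3)
        assert s == [15]

    def test_p_one_selects_all(self, rng):
        ghosts = make_ghosts(rng.standard_normal((4, 2)), [4])
        idx, s = select_nearest_ghosts(rng.standard_normal((3, 2)), ghosts, 1.0)
        assert s == [4]
        np.testing.assert_array_equal(np.sort(idx[0], axis=1), [[0, 1, 2, 3]] * 3)

    def test_identical_ghost_always_selected(self, rng):
        U = rng.standard_normal((10, 3))
        ghosts = make_ghosts(U, [10])
        idx, _ = select_nearest_ghosts(U[4][None, :], ghosts, 0.1)
        assert 4 in idx[0][0]

    def test_tie_breaks_toward_lower_index(self):
        # ghosts 0 and 1 identical: rank ties resolve to ghost 0
        U = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        ghosts = make_ghosts(U, [3])
        idx, _ = select_nearest_ghosts(np.array([[2.0, 0.1]]), ghosts, 0.34)
        assert idx[0][0, 0] == 0


class TestSimplexProjection:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=8)
    )
    def test_projection_is_feasible_and_optimal(self, vals):
        v = np.array(vals)
        z = project_simplex(v)
        assert z.min() >= 0
        assert z.sum() == pytest.approx(1.0, abs=1e-9)
        # optimality: no feasible random perturbation gets closer to v
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.dirichlet(np.ones(len(v)))
            assert np.sum((z - v) ** 2) <= np.sum((w - v) ** 2) + 1e-9


class TestLAEWeights:
    def test_single_anchor_forced(self, rng):
        z, ok = lae_weights(rng.standard_normal(3), rng.standard_normal((1, 3)))
        assert ok and z == pytest.approx([1.0])

    def test_vertex_solution(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        z, _ = lae_weights(np.array([1.0, 0.0]), U)
        np.testing.assert_allclose(z, [1.0, 0.0], atol=1e-6)

    def test_interior_solution(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        z, _ = lae_weights(np.array([0.3, 0.7]), U)
        np.testing.assert_allclose(z, [0.3, 0.7], atol=1e-6)

    def test_never_worse_than_best_vertex(self, rng):
        for _ in range(30):
            U = rng.standard_normal((4, 3))
            x = rng.standard_normal(3)
            z, _ = lae_weights(x, U)
            f = 0.5 * np.sum((x - U.T @ z) ** 2)
            best_vertex = min(
                0.5 * np.sum((x - U[i]) ** 2) for i in range(4)
            )
            assert f <= best_vertex + 1e-9

    def test_matches_exact_qp_oracle(self, rng):
        for _ in range(50):
            s = rng.integers(1, 5)
            d = rng.integers(1, 6)
            U = rng.standard_normal((s, d))
            x = rng.standard_normal(d)
            z, _ = lae_weights(x, U)
            _, f_star = simplex_qp_oracle(x, U)
            f = 0.5 * np.sum((x - U.T @ z) ** 2)
            assert f <= f_star + 1e-4
            assert z.min() >= -1e-12
            assert z.sum() == pytest.approx(1.0, abs=1e-8)


class TestBuildSparseEncoding:
    def test_cells_on_ghosts_one_hot(self):
        U = np.array([[2.0, 0.0], [0.0, 2.0], [-2.0, -2.0]])
        ghosts = make_ghosts(U, [3])
        enc = build_sparse_encoding(U.copy(), ghosts, p=0.67)
        Z = enc.Z.toarray()
        np.testing.assert_allclose(Z, np.eye(3)[..., :3], atol=1e-6)

    def test_two_batches_unit_sum_blocks(self, rng):
        U = rng.standard_normal((6, 3))
        ghosts = make_ghosts(U, [4, 2])
        X = rng.standard_normal((5, 3))
        enc = build_sparse_encoding(X, ghosts, p=0.5)
        Z = enc.Z.toarray()
        np.testing.assert_allclose(Z[:, :4].sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(Z[:, 4:].sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(Z.sum(axis=1), 2.0, atol=1e-8)
        assert Z.min() >= -1e-12

    def test_support_confined_to_selected_neighbors(self, rng):
        U = rng.standard_normal((8, 3))
        ghosts = make_ghosts(U, [8])
        X = rng.standard_normal((6, 3))
        enc = build_sparse_encoding(X, ghosts, p=0.25)
        Z = enc.Z.toarray()
        for i in range(6):
            outside = np.setdiff1d(np.arange(8), enc.neighbor_index[0][i])
            assert np.all(Z[i, outside] == 0)

    def test_rows_match_per_row_qp_oracle(self, rng):
        U = rng.standard_normal((5, 3))
        ghosts = make_ghosts(U, [5])
        X = rng.standard_normal((4, 3))
        enc = build_sparse_encoding(X, ghosts, p=0.6)  # s = 3
        Z = enc.Z.toarray()
        for i in range(4):
            sel = enc.neighbor_index[0][i]
            _, f_star = simplex_qp_oracle(X[i], U[sel])
            f = 0.5 * np.sum((X[i] - U[sel].T @ Z[i, sel]) ** 2)
            assert f <= f_star + 1e-4

    def test_dimension_mismatch_rejected(self, rng):
        ghosts = make_ghosts(rng.standard_normal((3, 4)), [3])
        with pytest.raises(GraphError, match="dimension"):
            build_sparse_encoding(rng.standard_normal((2, 3)), ghosts)
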