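"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from anchorcell.io import Batch, ExpressionBundle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_bundle():
    """Two batches, 3 genes, small integer counts."""
    return ExpressionBundle(
        batches=[
            Batch(
                matrix=np.array([[9.0, 0.0, 1.0], [9.0, 2.0, 0.0]]),
                cell_ids=["a1", "a2"],
                batch_id="A",
            ),
            Batch(
                matrix=np.array([[0.0, 3.0, 5.0]]),
                cell_ids=["b1"],
                batch_id="B",
            ),
        ],
        gene_ids=["g1", "g2", "g3"],
    )


def simplex_qp_oracle(x: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact minimizer of 1/2||x - U^T z||^2 on the probability simplex.

    Active-set enumeration: for every non-empty support S, solve the
    equality-constrained KKT system restricted to S and keep the best
    feasible solution.  Exact for any s, practical for s <= ~10.
    """
    s = U.shape[0]
    G = U @ U.T
    b = U @ x
    best_z, best_f = None, np.inf
    for r in range(1, s + 1):
        for S in itertools.combinations(range(s), r):
            S = list(S)
            K = np.zeros((r + 1, r + 1))
            K[:r, :r] = G[np.ix_(S, S)]
            K[:r, r] = 1.0
            K[r, :r] = 1.0
            rhs = np.append(b[S], 1.0)
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            z_S = sol[:r]
            if np.any(z_S < -1e-10):
                continue
            z = np.zeros(s)
            z[S] = np.clip(z_S, 0.0, None)
            z /= z.sum()
            resid = x - U.T @ z
            f = 0.5 * float(resid @ resid)
            if f < best_f:
                best_f, best_z = f, z
    return best_z, best_f


def brute_force_best_tree(A: np.ndarray) -> tuple[float, set[frozenset]]:
    """Maximum-total-similarity spanning tree by exhaustive enumeration."""
    import networkx as nx

    c = A.shape[0]
    edges = list(itertools.combinations(range(c), 2))
    best_w, best_set = -np.inf, None
    for subset in itertools.combinations(edges, c - 1):
        G = nx.Graph(subset)
        if G.number_of_nodes() == c and nx.is_connected(G):
            w = sum(A[u, v] for u, v in subset)
            if w > best_w:
                best_w = w
                best_set = {frozenset(e) for e in subset}
    return best_w, best_set
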