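"""Sparse bipartite cell-to-ghost graph with LAE-optimized edge weights.

Each cell is connected to its s_h most cosine-similar ghosts in every batch's
ghost set; the edge weights within each batch block are obtained by local
anchor embedding (LAE): the simplex-constrained least-squares reconstruction

    min_z 1/2 || x - U_sel^T z ||^2   s.t.  z >= 0,  sum(z) = 1,

solved by accelerated projected gradient (FISTA) with Euclidean projection
onto the probability simplex.  The result is an N x m sparse matrix Z whose
per-batch row blocks each sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .ghosts import GhostSet


class GraphError(ValueError):
    pass


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors; 0 if either is all-zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GraphError(f"length mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(norms > 0, X / norms, 0.0)
    return out


def select_nearest_ghosts(
    Xr: np.ndarray, ghosts: GhostSet, p: float
) -> tuple[list[np.ndarray], list[int]]:
    """Per cell and per batch, the indices of the s_h most similar ghosts.

    s_h = ceil(p * m_h), clamped to [1, m_h].  Similarity is cosine; ties at
    the cutoff are broken toward the lower ghost index (global index into U).

    Returns
    -------
    neighbor_index
        One (N x s_h) integer array per batch, with global ghost indices.
    s_list
        The s_h actually used per batch.
    """
    if not (0.0 < p <= 1.0):
        raise GraphError(f"p={p} must lie in (0, 1]")
    Xn = _unit_rows(np.asarray(Xr, dtype=float))
    neighbor_index: list[np.ndarray] = []
    s_list: list[int] = []
    for h in range(len(ghosts.m_h)):
        m_b = ghosts.m_h[h]
        off = ghosts.batch_offsets[h]
        s = int(np.ceil(p * m_b))
        s = min(max(s, 1), m_b)
        sims = Xn @ _unit_rows(ghosts.batch_block(h)).T  # N x m_b
        # stable argsort on -sims: equal similarities keep ascending index
        order = np.argsort(-sims, axis=1, kind="stable")[:, :s]
        neighbor_index.append(np.sort(order, axis=1) + off)
        s_list.append(s)
    return neighbor_index, s_list


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (O(s log s))."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    ind = np.arange(1, len(v) + 1)
    cond = u - css / ind > 0
    rho = ind[cond][-1]
    theta = css[cond][-1] / rho
    return np.maximum(v - theta, 0.0)


def lae_weights(
    x: np.ndarray,
    U_sel: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 300,
) -> tuple[np.ndarray, bool]:
    """Simplex-constrained least-squares weights for one cell.

    FISTA with fixed step 1/L, L the largest eigenvalue of U_sel U_sel^T.
    Returns the weight vector and a convergence flag; on non-convergence the
    best iterate found is returned.
    """
    x = np.asarray(x, dtype=float)
    U_sel = np.asarray(U_sel, dtype=float)
    s = U_sel.shape[0]
    if s == 1:
        return np.array([1.0]), True
    G = U_sel @ U_sel.T
    b = U_sel @ x
    L = float(np.linalg.eigvalsh(G)[-1])
    if L <= 0:  # all anchors at the origin: objective is constant
        return np.full(s, 1.0 / s), True

    def obj(z: np.ndarray) -> float:
        r = x - U_sel.T @ z
        return 0.5 * float(r @ r)

    z = np.full(s, 1.0 / s)
    y = z.copy()
    t_mom = 1.0
    best = z
    best_obj = obj(z)
    converged = False
    for _ in range(max_iter):
        grad = G @ y - b
        z_new = project_simplex(y - grad / L)
        f_new = obj(z_new)
        if f_new < best_obj:
            best, best_obj = z_new, f_new
        # optimality via the projected-gradient residual at the new point
        pg = z_new - project_simplex(z_new - (G @ z_new - b) / L)
        if np.max(np.abs(pg)) < tol:
            converged = True
            best, best_obj = z_new, f_new
            break
        if f_new > obj(z) + 1e-15:  # adaptive restart kills momentum ripple
            t_mom = 1.0
            y = z_new.copy()
        else:
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom)) / 2.0
            y = z_new + ((t_mom - 1.0) / t_new) * (z_new - z)
            t_mom = t_new
        z = z_new
    return (best, converged)


@dataclass
class SparseEncoding:
    """N x m sparse edge-weight matrix with per-batch unit-sum row blocks."""

    Z: sp.csr_matrix  # N x m, non-negative
    neighbor_index: list[np.ndarray]  # per batch: N x s_h global ghost indices
    s_h: list[int]
    p: float

    @property
    def N(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]


def build_sparse_encoding(
    Xr: np.ndarray,
    ghosts: GhostSet,
    p: float = 0.3,
    tol: float = 1e-7,
    max_iter: int = 300,
) -> SparseEncoding:
    """Assemble Z row by row: LAE weights at each cell's selected ghosts.

    Each batch block of a row is its own simplex (weights >= 0, summing to 1
    over that batch's selected ghosts); entries outside the selected
    neighborhoods are exactly zero.
    """
    Xr = np.asarray(Xr, dtype=float)
    if Xr.shape[1] != ghosts.d:
        raise GraphError(
            f"reduced dimension {Xr.shape[1]} != ghost dimension {ghosts.d}"
        )
    neighbor_index, s_list = select_nearest_ghosts(Xr, ghosts, p)
    n = Xr.shape[0]
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for h, (idx_mat, _s) in enumerate(zip(neighbor_index, s_list)):
        for i in range(n):
            idx = idx_mat[i]
            z, _ = lae_weights(Xr[i], ghosts.U[idx], tol=tol, max_iter=max_iter)
            rows.append(np.full(len(idx), i))
            cols.append(idx)
            vals.append(z)
    Z = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, ghosts.m),
    )
    return SparseEncoding(Z=Z, neighbor_index=neighbor_index, s_h=s_list, p=p)
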