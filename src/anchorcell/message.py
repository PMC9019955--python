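"""Message passing between ghost cells and the final row-normalized embedding.

The cell-to-ghost weights Z are smoothed through the symmetrically normalized
ghost-to-ghost similarity graph:

    Z_ghost = Z^T Z
    D_kk    = sum_i Z_ghost[i, k]
    Z_G     = D^{-1/2} Z_ghost D^{-1/2}
    Z_W     = Z Z_G

and each row of Z_W is scaled to unit L2 norm, giving the final sparse
embedding Z_norm shared by all downstream analyses.  One round of smoothing
is applied.  Ghosts with zero degree contribute nothing (their D^{-1/2}
entry is taken as 0, the pseudo-inverse convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import SparseEncoding


class MessagePassingError(ValueError):
    pass


@dataclass
class Embedding:
    """Final embedding plus the intermediate message-passing matrices."""

    Z_norm: np.ndarray  # N x m, rows unit L2 (or zero)
    Z_ghost: sp.csr_matrix  # m x m
    D: np.ndarray  # m degree entries
    Z_G: sp.csr_matrix  # m x m, symmetric
    Z_W: np.ndarray  # N x m

    @property
    def N(self) -> int:
        return self.Z_norm.shape[0]

    @property
    def m(self) -> int:
        return self.Z_norm.shape[1]


def row_normalize(Z_W: np.ndarray) -> np.ndarray:
    """Scale each row to unit L2 norm; all-zero rows stay zero (warned)."""
    Z_W = np.asarray(Z_W, dtype=float)
    norms = np.linalg.norm(Z_W, axis=1, keepdims=True)
    if np.any(norms == 0):
        warnings.warn(
            f"{int((norms == 0).sum())} all-zero embedding rows left at zero",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(norms > 0, Z_W / norms, 0.0)


def message_pass(Z: SparseEncoding | sp.spmatrix | np.ndarray) -> Embedding:
    """One round of ghost-graph smoothing followed by row normalization."""
    if isinstance(Z, SparseEncoding):
        Zs = Z.Z
    else:
        Zs = sp.csr_matrix(Z)
    if Zs.nnz and Zs.data.min() < 0:
        raise MessagePassingError("Z must be non-negative")

    Z_ghost = (Zs.T @ Zs).tocsr()
    D = np.asarray(Z_ghost.sum(axis=0)).ravel()
    d_inv_sqrt = np.zeros_like(D)
    pos = D > 0
    d_inv_sqrt[pos] = 1.0 / np.sqrt(D[pos])
    Dinv = sp.diags(d_inv_sqrt)
    Z_G = (Dinv @ Z_ghost @ Dinv).tocsr()
    Z_W = np.asarray((Zs @ Z_G).todense())
    return Embedding(
        Z_norm=row_normalize(Z_W),
        Z_ghost=Z_ghost,
        D=D,
        Z_G=Z_G,
        Z_W=Z_W,
    )
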