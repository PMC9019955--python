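"""Dimension reduction: online fast similarity matching (FSM) and PCA.

Both methods map the normalized cells-by-genes matrix X (N x M) to an N x d
representation X' whose pairwise inner products approximate those of X, i.e.
they approximately minimize the similarity-matching objective

    || X X^T - X' X'^T ||_F^2 .

FSM does this with streaming Hebbian/anti-Hebbian updates, visiting one cell
at a time; its fixed point spans the top-d principal subspace of the
(uncentered) second-moment matrix.  PCA is offered as the conventional
alternative and is exact; it centers columns first, whereas FSM operates on
X as given because the objective is defined on raw inner products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from sklearn.decomposition import PCA


class ReductionError(ValueError):
    pass


@dataclass
class ReducedMatrix:
    """d-dimensional cell representations plus the fitted transform."""

    values: np.ndarray  # N x d
    d: int
    method: str  # "fsm" | "pca"
    projection_state: dict[str, Any]
    objective: float | None = None  # ||XX^T - X'X'^T||_F recorded at fit

    @property
    def N(self) -> int:
        return self.values.shape[0]


def default_dim(M: int, N: int) -> int:
    """Recommended target dimension: ~M/100, within [30, 150], < min(N, M)."""
    d = int(round(M / 100.0))
    d = min(max(d, 30), 150)
    return max(1, min(d, min(N, M) - 1))


def gram_error(X: np.ndarray, Xp: np.ndarray) -> float:
    """Relative Frobenius error ||XX^T - X'X'^T||_F / ||XX^T||_F."""
    G = X @ X.T
    Gp = Xp @ Xp.T
    denom = np.linalg.norm(G)
    return float(np.linalg.norm(G - Gp) / denom) if denom > 0 else 0.0


def _check_inputs(X: np.ndarray, d: int) -> None:
    if not np.all(np.isfinite(X)):
        raise ReductionError("input matrix contains non-finite values")
    n, m = X.shape
    if d < 1 or d > min(n, m):
        raise ReductionError(f"d={d} must satisfy 1 <= d <= min(N, M)={min(n, m)}")


def reduce_fsm(
    X: np.ndarray,
    d: int,
    epochs: int = 30,
    seed: int = 0,
    learning_offset: float = 20.0,
) -> ReducedMatrix:
    """Online fast similarity matching.

    Maintains a feed-forward weight matrix ``W`` (d x M) and the inverse of
    the lateral matrix ``M_lat`` (d x d).  For each streamed cell x the output
    is y = M_lat^{-1} W x, followed by the Hebbian update of W toward
    E[y x^T] and the anti-Hebbian update of M_lat toward E[y y^T]; the
    inverse is maintained directly via Sherman-Morrison, which is what makes
    the per-sample cost O(d*M).  The learning rate decays as 1/(t + t0).

    After the streaming passes the final linear map F = M_lat^{-1} W is
    applied to all rows at once, so ``projection_state`` reduces to a single
    d x M matrix usable on new cells.
    """
    X = np.asarray(X, dtype=float)
    _check_inputs(X, d)
    if epochs < 1:
        raise ReductionError("epochs must be >= 1")
    n, m = X.shape
    rng = np.random.default_rng(seed)

    # scale rows to ~unit norm during fitting: the streaming transient is
    # scale sensitive (W starts at a fixed scale) but the learned linear map
    # F is scale equivariant, so it applies to X unchanged afterwards
    row_scale = float(np.mean(np.linalg.norm(X, axis=1)))
    Xs = X / row_scale if row_scale > 0 else X

    # small random orthonormal init keeps early outputs bounded
    W = rng.standard_normal((d, m))
    W, _ = np.linalg.qr(W.T)
    W = W.T * 0.1
    Minv = np.eye(d)

    t = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in order:
            x = Xs[i]
            y = Minv @ (W @ x)
            eta = 1.0 / (t + learning_offset)
            # Hebbian: W <- (1-2eta) W + 2eta y x^T
            W += 2.0 * eta * (np.outer(y, x) - W)
            # anti-Hebbian: M_lat <- (1-2eta) M_lat + 2eta y y^T, kept as
            # its inverse via Sherman-Morrison (the "fast" update)
            eta_m = 2.0 * eta
            Ainv = Minv / (1.0 - eta_m)
            Ay = Ainv @ y
            Minv = Ainv - np.outer(Ay, Ay) * (eta_m / (1.0 + eta_m * (y @ Ay)))
            Minv = 0.5 * (Minv + Minv.T)  # keep symmetric against drift
            t += 1

    F = Minv @ W
    Xp = X @ F.T
    obj = float(np.linalg.norm(X @ X.T - Xp @ Xp.T))
    return ReducedMatrix(
        values=Xp,
        d=d,
        method="fsm",
        projection_state={"method": "fsm", "F": F, "M": m},
        objective=obj,
    )


def reduce_pca(X: np.ndarray, d: int, seed: int = 0) -> ReducedMatrix:
    """Top-d principal-component scores of the column-centered matrix."""
    X = np.asarray(X, dtype=float)
    _check_inputs(X, d)
    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    Xp = pca.fit_transform(X)
    obj = float(np.linalg.norm(X @ X.T - Xp @ Xp.T))
    return ReducedMatrix(
        values=Xp,
        d=d,
        method="pca",
        projection_state={
            "method": "pca",
            "mean": pca.mean_,
            "components": pca.components_,
            "M": X.shape[1],
        },
        objective=obj,
    )


def project_new(state: dict[str, Any], X_new: np.ndarray) -> np.ndarray:
    """Project new cells with a previously fitted transform (no refitting)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != state["M"]:
        raise ReductionError(
            f"new matrix has {X_new.shape[1]} genes; transform was fitted on "
            f"{state['M']}"
        )
    if state["method"] == "fsm":
        return X_new @ state["F"].T
    if state["method"] == "pca":
        return (X_new - state["mean"]) @ state["components"].T
    raise ReductionError(f"unknown projection method {state['method']!r}")


def reduce(
    X: np.ndarray,
    d: int,
    method: str = "fsm",
    seed: int = 0,
    epochs: int = 30,
) -> ReducedMatrix:
    """Dispatch to :func:`reduce_fsm` or :func:`reduce_pca`."""
    if method == "fsm":
        return reduce_fsm(X, d, epochs=epochs, seed=seed)
    if method == "pca":
        return reduce_pca(X, d, seed=seed)
    raise ReductionError(f"unknown reduction method {method!r}")
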