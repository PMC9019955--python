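"""Reference-based cell-type inference (label transfer).

A labeled reference dataset is run through the full encoding pipeline once;
the fitted projection, the ghost set, the ghost-graph operator Z_G and a
linear max-margin classifier trained on the smoothed reference weights
Z_W are packaged as a reusable model.  New ("inference") cells are then
normalized with their own column sums, projected with the reference
transform, encoded against the *reference* ghosts and smoothed with the
*reference* Z_G — the reference embedding is never recomputed — before the
classifier assigns labels.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import scipy.sparse as sp
from sklearn.svm import LinearSVC

from .ghosts import GhostSet, default_m, find_ghost_cells
from .graph import build_sparse_encoding, lae_weights, select_nearest_ghosts
from .io import ExpressionBundle, log_normalize
from .message import message_pass
from .reduction import default_dim, project_new, reduce


class InferenceError(ValueError):
    pass


@dataclass
class ReferenceModel:
    projection_state: dict[str, Any]
    ghosts: GhostSet
    Z_G: sp.csr_matrix
    classifier: LinearSVC
    label_vocabulary: list[str]
    gene_ids: list[str]
    p: float
    d: int
    m_h: list[int]
    Z_W_refer: np.ndarray
    ref_colsums: np.ndarray | None = None  # pooled sums of log10(r+1) per gene

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ReferenceModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def build_reference(
    bundle: ExpressionBundle,
    labels: np.ndarray,
    d: int | None = None,
    m_h: list[int] | int | None = None,
    p: float = 0.3,
    method: str = "fsm",
    seed: int = 0,
) -> ReferenceModel:
    """Fit the full pipeline on labeled reference cells and train the SVM.

    The classifier is a linear one-vs-rest max-margin model (unit
    regularization, balanced class weights) on the smoothed weights Z_W.
    """
    labels = np.asarray(labels)
    if len(labels) != bundle.N:
        raise InferenceError("every reference cell must be labeled")
    vocab = sorted(str(v) for v in np.unique(labels))
    for v in vocab:
        if np.sum(labels.astype(str) == v) < 2:
            import warnings

            warnings.warn(
                f"label {v!r} has fewer than 2 cells; it may be unlearnable",
                stacklevel=2,
            )

    norm = log_normalize(bundle)
    if d is None:
        d = default_dim(norm.M, norm.N)
    red = reduce(norm.values, d, method=method, seed=seed)
    if m_h is None:
        m_h = [default_m(n) for n in bundle.N_h]
    ghosts = find_ghost_cells(red.values, bundle.N_h, m_h, seed=seed)
    enc = build_sparse_encoding(red.values, ghosts, p=p)
    emb = message_pass(enc)

    clf = LinearSVC(C=1.0, class_weight="balanced", random_state=seed, max_iter=5000)
    if len(vocab) == 1:
        # degenerate single-class reference: predict the class always
        clf = _ConstantClassifier(vocab[0])  # type: ignore[assignment]
    else:
        clf.fit(emb.Z_W, labels.astype(str))
    return ReferenceModel(
        projection_state=red.projection_state,
        ghosts=ghosts,
        Z_G=emb.Z_G,
        classifier=clf,
        label_vocabulary=vocab,
        gene_ids=list(norm.gene_ids),
        p=p,
        d=d,
        m_h=ghosts.m_h,
        Z_W_refer=emb.Z_W,
        ref_colsums=np.vstack(
            [np.log10(b.matrix + 1.0).sum(axis=0) for b in bundle.batches]
        ).sum(axis=0),
    )


class _ConstantClassifier:
    def __init__(self, label: str):
        self.label = label

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.label, dtype=object)


def map_inference_cells(
    model: ReferenceModel,
    new_bundle: ExpressionBundle,
    normalization: str = "own",
) -> np.ndarray:
    """Embed new cells into the reference latent space (Z_W rows).

    New cells are normalized, projected with the reference transform,
    connected to the reference ghost set by LAE weights, and smoothed with
    the stored reference ghost-graph operator.  ``normalization="own"``
    (default) scales gene columns by the inference batch's own column sums;
    ``"reference"`` reuses the pooled reference column sums, which makes a
    cell copied verbatim from a single-batch reference embed identically.
    """
    missing = [g for g in model.gene_ids if g not in set(new_bundle.gene_ids)]
    if missing:
        shown = ", ".join(missing[:5])
        raise InferenceError(
            f"{len(missing)} reference genes missing from the inference set "
            f"(e.g. {shown}); align gene sets first"
        )
    pos = {g: i for i, g in enumerate(new_bundle.gene_ids)}
    idx = np.array([pos[g] for g in model.gene_ids], dtype=int)
    reordered = ExpressionBundle(
        batches=[
            type(b)(matrix=b.matrix[:, idx], cell_ids=b.cell_ids, batch_id=b.batch_id)
            for b in new_bundle.batches
        ],
        gene_ids=list(model.gene_ids),
    )
    if normalization == "own":
        values = log_normalize(reordered).values
    elif normalization == "reference":
        if model.ref_colsums is None:
            raise InferenceError("model lacks stored reference column sums")
        r = np.log10(
            np.vstack([b.matrix for b in reordered.batches]) + 1.0
        )
        colsum = model.ref_colsums
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(colsum > 0, r / np.sqrt(colsum), 0.0)
    else:
        raise InferenceError(f"unknown normalization {normalization!r}")
    Xr = project_new(model.projection_state, values)
    neighbor_index, _ = select_nearest_ghosts(Xr, model.ghosts, model.p)
    n = Xr.shape[0]
    rows, cols, vals = [], [], []
    for idx_mat in neighbor_index:
        for i in range(n):
            sel = idx_mat[i]
            z, _ = lae_weights(Xr[i], model.ghosts.U[sel])
            rows.append(np.full(len(sel), i))
            cols.append(sel)
            vals.append(z)
    Z = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, model.ghosts.m),
    )
    return np.asarray((Z @ model.Z_G).todense())


def predict_labels(model: ReferenceModel, Z_infer: np.ndarray) -> np.ndarray:
    """Classifier decision per embedded inference row (deterministic)."""
    Z_infer = np.asarray(Z_infer, dtype=float)
    if Z_infer.size == 0:
        return np.array([], dtype=object)
    if Z_infer.shape[1] != model.ghosts.m:
        raise InferenceError(
            f"embedding has {Z_infer.shape[1]} columns; reference uses "
            f"{model.ghosts.m} ghosts"
        )
    return np.asarray(model.classifier.predict(Z_infer))
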