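"""Cell clustering on the sparse embedding and variance-ratio DE ranking."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


class DownstreamError(ValueError):
    pass


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-cell integer ids in [0, k)
    k: int
    algorithm: str = "kmeans"


def cluster_cells(
    Z_norm: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> ClusterResult:
    """K-means on the embedding rows (k-means++ init, fixed seed)."""
    Z_norm = np.asarray(Z_norm, dtype=float)
    n = Z_norm.shape[0]
    if k < 1 or k > n:
        raise DownstreamError(f"k={k} must satisfy 1 <= k <= N={n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z_norm)
    return ClusterResult(labels=labels, k=k, algorithm="kmeans")


def de_statistic(X: np.ndarray, in_cluster: np.ndarray) -> np.ndarray:
    """Variance-ratio statistic for one cluster against its complement.

    For gene j with global mean x_bar_j and population variance v_j,

        T_j = (mean_{in} x_ij - mean_{out} x_ij)^2 / v_j ,

    with T_j := 0 for genes of zero global variance.  The squared mean
    difference over the pooled population variance makes T invariant to
    shifting a gene column by a constant and to rescaling it.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n_c = int(in_cluster.sum())
    if n_c == 0 or n_c == n:
        raise DownstreamError("cluster and its complement must be non-empty")
    mean_in = X[in_cluster].mean(axis=0)
    mean_out = X[~in_cluster].mean(axis=0)
    var = X.var(axis=0)  # population (1/N) variance
    num = (mean_in - mean_out) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(var > 0, num / var, 0.0)
    return T


@dataclass
class DEResult:
    """Per-cluster ranked gene tables (gene_id, T, rank)."""

    tables: dict[int, pd.DataFrame]
    statistics: dict[int, np.ndarray]  # full T vector per cluster
    gene_ids: list[str]

    def top_genes(self, cluster: int) -> list[str]:
        return list(self.tables[cluster]["gene_id"])


def differential_genes(
    X: np.ndarray,
    labels: ClusterResult | np.ndarray,
    gene_ids: list[str] | None = None,
    top_k: int = 20,
) -> DEResult:
    """Rank genes per cluster by the variance-ratio statistic.

    ``X`` is the normalized expression matrix (rows aligned with ``labels``).
    Ties in T are broken by gene id for determinism.
    """
    lab = labels.labels if isinstance(labels, ClusterResult) else np.asarray(labels)
    X = np.asarray(X, dtype=float)
    if len(lab) != X.shape[0]:
        raise DownstreamError("labels must cover every row of X")
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(X.shape[1])]
    tables: dict[int, pd.DataFrame] = {}
    stats: dict[int, np.ndarray] = {}
    for c in np.unique(lab):
        T = de_statistic(X, lab == c)
        df = pd.DataFrame({"gene_id": gene_ids, "T": T})
        df = df.sort_values(
            ["T", "gene_id"], ascending=[False, True], kind="stable"
        ).head(top_k)
        df["rank"] = np.arange(1, len(df) + 1)
        tables[int(c)] = df.reset_index(drop=True)
        stats[int(c)] = T
    return DEResult(tables=tables, statistics=stats, gene_ids=list(gene_ids))
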