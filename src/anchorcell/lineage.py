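"""Trajectory and pseudotime inference on the sparse embedding.

Cell-type clusters are linked into a lineage tree: the cluster-to-cluster
similarity A averages all pairwise cell-cell cosine similarities between two
clusters, and the spanning tree connecting the most similar clusters is the
minimum spanning tree on the transformed weights w = 1 - A.  Orienting the
tree away from a root cluster (the least differentiated cell type) fixes the
lineage direction.  Pseudotime then accumulates Euclidean distance in the
embedding: each cluster gets a landmark root cell, path lengths between
landmarks are summed along the lineage, and every cell adds its distance to
its own cluster's landmark; min-max normalization maps the result to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import networkx as nx
import numpy as np

from .downstream import ClusterResult


class LineageError(ValueError):
    pass


def _labels_array(labels: ClusterResult | np.ndarray) -> np.ndarray:
    return labels.labels if isinstance(labels, ClusterResult) else np.asarray(labels)


def cluster_similarity_matrix(
    Z_norm: np.ndarray, labels: ClusterResult | np.ndarray
) -> np.ndarray:
    """A[p, q] = average pairwise cosine similarity between clusters p and q.

    Because cosine is bilinear in the unit-scaled rows, the double sum
    collapses to an inner product of per-cluster means of unit rows; a
    brute-force double loop is kept as the test oracle.
    """
    Z = np.asarray(Z_norm, dtype=float)
    lab = _labels_array(labels)
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        Zu = np.where(norms > 0, Z / norms, 0.0)
    clusters = np.unique(lab)
    means = []
    for c in clusters:
        rows = Zu[lab == c]
        if rows.shape[0] == 0:
            raise LineageError(f"cluster {c} is empty")
        means.append(rows.mean(axis=0))
    means_arr = np.vstack(means)
    return means_arr @ means_arr.T


@dataclass
class TrajectoryGraph:
    A: np.ndarray  # c x c cluster similarity
    tree_edges: list[tuple[int, int]]  # undirected, cluster-index pairs
    root_cluster: int
    parent: dict[int, int | None]  # directed away from root
    order: list[int]  # BFS order from root
    clusters: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def c(self) -> int:
        return self.A.shape[0]

    def depth(self) -> dict[int, int]:
        d = {self.root_cluster: 0}
        for node in self.order:
            if node == self.root_cluster:
                continue
            d[node] = d[self.parent[node]] + 1
        return d


def infer_trajectory(
    A: np.ndarray, root_cluster: int | str = "auto"
) -> TrajectoryGraph:
    """Spanning tree over clusters connecting the most similar ones.

    Computed as the minimum spanning tree on w = 1 - A (equivalently the
    maximum-similarity spanning tree), then oriented away from the root.
    With ``root_cluster="auto"`` the root is a maximum-eccentricity node of
    the tree (a lineage endpoint), ties broken by the lowest cluster index —
    a heuristic for the least-differentiated cell type sitting at an extreme
    of the differentiation path.
    """
    A = np.asarray(A, dtype=float)
    c = A.shape[0]
    if A.shape != (c, c) or not np.allclose(A, A.T, atol=1e-8):
        raise LineageError("A must be a symmetric square matrix")
    if c < 2:
        raise LineageError("need at least two clusters for a trajectory")
    G = nx.Graph()
    G.add_nodes_from(range(c))
    for p in range(c):
        for q in range(p + 1, c):
            G.add_edge(p, q, weight=1.0 - A[p, q])
    T = nx.minimum_spanning_tree(G, algorithm="kruskal")
    if root_cluster == "auto":
        ecc = nx.eccentricity(T)
        max_e = max(ecc.values())
        root = min(n for n, e in ecc.items() if e == max_e)
    else:
        root = int(root_cluster)
        if root not in T:
            raise LineageError(f"root cluster {root} not in [0, {c})")
    parent: dict[int, int | None] = {root: None}
    order = [root]
    for u, v in nx.bfs_edges(T, root):
        parent[v] = u
        order.append(v)
    return TrajectoryGraph(
        A=A,
        tree_edges=sorted(tuple(sorted(e)) for e in T.edges),
        root_cluster=root,
        parent=parent,
        order=order,
        clusters=np.arange(c),
    )


def select_root_cell(
    Z_norm: np.ndarray,
    labels: ClusterResult | np.ndarray,
    tree: TrajectoryGraph,
) -> int:
    """Pick the root cluster's cell that best anchors the lineage ordering.

    For each candidate cell in the root cluster, the Pearson correlation is
    taken between its Euclidean distances to all cells and those cells'
    cluster hop-depth from the root; the cell with the highest correlation
    wins (ties and degenerate correlations fall back to the lowest index).
    """
    Z = np.asarray(Z_norm, dtype=float)
    lab = _labels_array(labels)
    depth = tree.depth()
    depth_per_cell = np.array([depth[int(c)] for c in lab], dtype=float)
    candidates = np.flatnonzero(lab == tree.root_cluster)
    if len(candidates) == 0:
        raise LineageError("root cluster has no cells")
    if len(candidates) == 1:
        return int(candidates[0])
    best_idx = int(candidates[0])
    best_score = -np.inf
    dstd = depth_per_cell.std()
    for i in candidates:
        dist = np.linalg.norm(Z - Z[i], axis=1)
        if dstd == 0 or dist.std() == 0:
            score = -np.inf
        else:
            score = float(np.corrcoef(dist, depth_per_cell)[0, 1])
        if score > best_score:
            best_score = score
            best_idx = int(i)
    return best_idx


@dataclass
class PseudotimeResult:
    root_cells: dict[int, int]  # cluster -> cell index of its landmark
    D: np.ndarray  # per-cell accumulated distance
    D_norm: np.ndarray  # per-cell pseudotime in [0, 1]


def compute_pseudotime(
    Z_norm: np.ndarray,
    labels: ClusterResult | np.ndarray,
    tree: TrajectoryGraph,
    root_cell: int,
) -> PseudotimeResult:
    """Accumulated-distance pseudotime along the rooted lineage tree.

    Each non-root cluster's landmark is its cell with the smallest average
    Euclidean distance to all cells of its parent cluster.  A cell's distance
    is its distance to its own cluster's landmark plus the summed
    landmark-to-landmark path length back to the root; min-max scaling gives
    the pseudotime.
    """
    Z = np.asarray(Z_norm, dtype=float)
    lab = _labels_array(labels)
    root_cells: dict[int, int] = {tree.root_cluster: int(root_cell)}
    for cl in tree.order:
        if cl == tree.root_cluster:
            continue
        par = tree.parent[cl]
        members = np.flatnonzero(lab == cl)
        parent_rows = Z[lab == par]
        # average distance from each candidate to every parent-cluster cell
        avg = np.array(
            [np.linalg.norm(parent_rows - Z[i], axis=1).mean() for i in members]
        )
        root_cells[cl] = int(members[int(np.argmin(avg))])

    # path length from the root landmark to each cluster's landmark
    path_len: dict[int, float] = {tree.root_cluster: 0.0}
    for cl in tree.order:
        if cl == tree.root_cluster:
            continue
        par = tree.parent[cl]
        step = float(np.linalg.norm(Z[root_cells[cl]] - Z[root_cells[par]]))
        path_len[cl] = path_len[par] + step

    D = np.empty(Z.shape[0])
    for cl in np.unique(lab):
        members = lab == cl
        landmark = Z[root_cells[int(cl)]]
        D[members] = (
            np.linalg.norm(Z[members] - landmark, axis=1) + path_len[int(cl)]
        )
    span = D.max() - D.min()
    if span == 0:
        warnings.warn("all cells equidistant; pseudotime set to 0", stacklevel=2)
        D_norm = np.zeros_like(D)
    else:
        D_norm = (D - D.min()) / span
    return PseudotimeResult(root_cells=root_cells, D=D, D_norm=D_norm)
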