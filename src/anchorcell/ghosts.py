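"""Ghost-cell identification: per-batch K-means centers in reduced space.

Ghost cells are hypothetical anchor points — K-means centroids of a batch's
reduced cell representations — standing in for small neighborhoods of real
cells.  No cell ever receives a persisted cluster label here; only the
centroid coordinates are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans


class GhostError(ValueError):
    pass


@dataclass
class GhostSet:
    """Stacked per-batch ghost (anchor) features.

    ``U`` holds all ghosts row-wise; ``batch_offsets[h]`` is the start index
    of batch h's block, so batch h owns rows
    ``batch_offsets[h] : batch_offsets[h] + m_h[h]``.
    """

    U: np.ndarray  # m x d
    m_h: list[int]
    batch_offsets: list[int]
    seed: int

    @property
    def m(self) -> int:
        return self.U.shape[0]

    @property
    def d(self) -> int:
        return self.U.shape[1]

    def batch_block(self, h: int) -> np.ndarray:
        off = self.batch_offsets[h]
        return self.U[off : off + self.m_h[h]]


def default_m(N_h: int) -> int:
    """Recommended ghosts per batch: ~N_h/100, within [20, 100], <= N_h."""
    if N_h < 1:
        raise GhostError("batch must contain at least one cell")
    m = int(round(N_h / 100.0))
    m = min(max(m, 20), 100)
    return min(m, N_h)


def find_ghost_cells(
    Xr: np.ndarray,
    batch_sizes: list[int],
    m_h: list[int] | int,
    seed: int = 0,
    n_init: int = 10,
) -> GhostSet:
    """Run K-means per batch on the reduced rows and stack the centers.

    A scalar ``m_h`` is applied to every batch.  K-means uses k-means++
    initialization with ``n_init`` restarts and a per-batch seed derived
    deterministically from ``seed``, so results are reproducible.
    """
    Xr = np.asarray(Xr, dtype=float)
    if sum(batch_sizes) != Xr.shape[0]:
        raise GhostError(
            f"batch sizes sum to {sum(batch_sizes)} but matrix has "
            f"{Xr.shape[0]} rows"
        )
    if isinstance(m_h, (int, np.integer)):
        m_list = [int(m_h)] * len(batch_sizes)
    else:
        m_list = [int(v) for v in m_h]
    if len(m_list) != len(batch_sizes):
        raise GhostError("m_h must be scalar or one value per batch")

    blocks: list[np.ndarray] = []
    offsets: list[int] = []
    start = 0
    total = 0
    for h, (n_b, k) in enumerate(zip(batch_sizes, m_list)):
        if n_b == 0:
            raise GhostError(f"batch {h} is empty")
        if k < 1:
            raise GhostError(f"m_h must be >= 1 (batch {h} got {k})")
        if k > n_b:
            raise GhostError(
                f"batch {h}: m_h={k} exceeds its {n_b} cells"
            )
        rows = Xr[start : start + n_b]
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_init,
            random_state=seed + h,
        ).fit(rows)
        blocks.append(km.cluster_centers_)
        offsets.append(total)
        total += k
        start += n_b
    return GhostSet(
        U=np.vstack(blocks), m_h=m_list, batch_offsets=offsets, seed=seed
    )
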