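"""Synthetic multi-batch scRNA-seq generator with full ground truth.

Counts are built from a latent-Gaussian construction: each cell type owns a
mean position in a low-dimensional latent space (mutually orthogonal
directions scaled by a separation parameter), cells scatter around it, and a
random loading matrix lifts the latent coordinates to per-gene log-rates.
On top of that sit per-batch additive log-scale offsets (the batch effect),
optional per-cluster marker-gene boosts (the DE ground truth), and Poisson
or negative-binomial count noise.  Because geometry (latent space) and DE
signal (marker boosts) are controlled independently, every pipeline stage
has a known truth to score against.

Trajectory mode replaces the discrete cluster means by positions along a 1-D
chain (or a branching tree) in latent space, with each cell's latent time
emitted as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Batch, ExpressionBundle


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Study conditions for the generator.

    Defaults emulate a two-batch integration task with well-separated cell
    types and a moderate technology shift: 300 cells per batch, 600 genes,
    4 cell types, latent separation 5.0 against within-type spread 1.0,
    batch offsets of s.d. 0.4 on the natural-log rate scale, and 10 marker
    genes per type boosted by +1.5 log units.
    """

    n_cells: tuple[int, ...] = (300, 300)
    n_genes: int = 600
    n_clusters: int = 4
    proportions: tuple[float, ...] | None = None  # per-cluster, shared
    latent_dim: int = 8
    separation: float = 5.0
    within_sd: float = 1.0
    loading_scale: float = 0.5
    batch_shift_sd: float = 0.4
    batch_scale_sd: float = 0.0  # optional multiplicative per-batch factor sd
    markers_per_cluster: int = 10
    marker_effect: float = 1.5  # natural-log fold boost in the home cluster
    batch_unique: dict[int, int] = field(default_factory=dict)
    # cluster -> batch index that exclusively hosts it
    trajectory: str = "none"  # none | chain | branch
    noise: str = "poisson"  # poisson | nb
    nb_dispersion: float = 0.2
    base_log_mean: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise SyntheticError("need at least one cluster")
        if any(n < 1 for n in self.n_cells):
            raise SyntheticError("each batch needs at least one cell")
        if self.proportions is not None:
            if len(self.proportions) != self.n_clusters:
                raise SyntheticError("one proportion per cluster required")
            if not np.isclose(sum(self.proportions), 1.0):
                raise SyntheticError("cluster proportions must sum to 1")
        if self.marker_effect < 0:
            raise SyntheticError("marker effect must be >= 0")
        if self.trajectory not in ("none", "chain", "branch"):
            raise SyntheticError(f"unknown trajectory mode {self.trajectory!r}")
        for c, b in self.batch_unique.items():
            if not (0 <= c < self.n_clusters) or not (0 <= b < len(self.n_cells)):
                raise SyntheticError("batch_unique references unknown cluster/batch")


@dataclass
class SyntheticTruth:
    labels: np.ndarray  # per-cell cluster id
    batch: np.ndarray  # per-cell batch id (string)
    time: np.ndarray | None  # per-cell latent time, trajectory modes only
    markers: dict[int, list[str]]  # cluster -> marker gene ids
    batch_unique: dict[int, int]


def _cluster_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Mutually orthogonal latent directions scaled by the separation."""
    q = max(spec.latent_dim, spec.n_clusters)
    raw = rng.standard_normal((q, q))
    Q, _ = np.linalg.qr(raw)
    return Q[: spec.n_clusters, : spec.latent_dim] * spec.separation


def _sample_counts(
    log_rate: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    rate = np.exp(np.clip(log_rate, -30, 12))
    if spec.noise == "poisson":
        return rng.poisson(rate).astype(float)
    if spec.noise == "nb":
        # gamma-Poisson mixture with shape 1/dispersion
        shape = 1.0 / spec.nb_dispersion
        lam = rng.gamma(shape, rate / shape)
        return rng.poisson(lam).astype(float)
    raise SyntheticError(f"unknown noise model {spec.noise!r}")


def _assemble(
    spec: SyntheticSpec,
    latent: list[np.ndarray],
    labels: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[ExpressionBundle, dict[int, list[str]]]:
    gene_ids = [f"gene{j:04d}" for j in range(spec.n_genes)]
    q = spec.latent_dim
    loadings = rng.standard_normal((q, spec.n_genes)) * (
        spec.loading_scale / np.sqrt(q)
    )
    base = spec.base_log_mean + rng.uniform(-0.5, 0.5, size=spec.n_genes)

    marker_sets: dict[int, list[str]] = {}
    marker_idx: dict[int, np.ndarray] = {}
    if spec.markers_per_cluster > 0:
        perm = rng.permutation(spec.n_genes)
        for c in range(spec.n_clusters):
            idx = perm[
                c * spec.markers_per_cluster : (c + 1) * spec.markers_per_cluster
            ]
            marker_idx[c] = idx
            marker_sets[c] = [gene_ids[j] for j in idx]

    batches: list[Batch] = []
    cell_counter = 0
    for b, (lat, lab) in enumerate(zip(latent, labels)):
        log_rate = base[None, :] + lat @ loadings
        if spec.batch_shift_sd > 0:
            log_rate = log_rate + rng.normal(
                0.0, spec.batch_shift_sd, size=spec.n_genes
            )[None, :]
        if spec.batch_scale_sd > 0:
            log_rate = log_rate * np.exp(
                rng.normal(0.0, spec.batch_scale_sd)
            )
        for c, idx in marker_idx.items():
            rows = lab == c
            if rows.any():
                log_rate[np.ix_(rows, idx)] += spec.marker_effect
        counts = _sample_counts(log_rate, spec, rng)
        ids = [f"cell{cell_counter + i:05d}" for i in range(lat.shape[0])]
        cell_counter += lat.shape[0]
        batches.append(Batch(matrix=counts, cell_ids=ids, batch_id=f"batch{b}"))
    return ExpressionBundle(batches=batches, gene_ids=gene_ids), marker_sets


def generate_batches(spec: SyntheticSpec) -> tuple[ExpressionBundle, SyntheticTruth]:
    """Draw a multi-batch count dataset with known cluster structure."""
    spec.validate()
    if spec.trajectory != "none":
        return generate_trajectory(spec)
    rng = np.random.default_rng(spec.seed)
    means = _cluster_means(spec, rng)

    latent: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for b, n_b in enumerate(spec.n_cells):
        allowed = [
            c
            for c in range(spec.n_clusters)
            if spec.batch_unique.get(c, b) == b
        ]
        if not allowed:
            raise SyntheticError(f"batch {b} has no allowed clusters")
        if spec.proportions is None:
            probs = np.full(len(allowed), 1.0 / len(allowed))
        else:
            probs = np.array([spec.proportions[c] for c in allowed])
            probs = probs / probs.sum()
        lab = rng.choice(allowed, size=n_b, p=probs)
        lat = means[lab] + rng.normal(0.0, spec.within_sd, size=(n_b, spec.latent_dim))
        latent.append(lat)
        labels.append(lab)

    bundle, markers = _assemble(spec, latent, labels, rng)
    truth = SyntheticTruth(
        labels=np.concatenate(labels),
        batch=bundle.batch_labels(),
        time=None,
        markers=markers,
        batch_unique=dict(spec.batch_unique),
    )
    return bundle, truth


def generate_trajectory(spec: SyntheticSpec) -> tuple[ExpressionBundle, SyntheticTruth]:
    """Cells along a latent chain (or branching tree) with known time.

    In chain mode the cluster means are colinear: cluster c sits at
    ``c * separation`` along one latent direction and a cell's latent time is
    its continuous coordinate along that line.  Branch mode forks the chain
    after the first segment into two diverging arms that share the common
    prefix path.
    """
    spec.validate()
    if spec.trajectory == "none":
        raise SyntheticError("trajectory mode must be 'chain' or 'branch'")
    rng = np.random.default_rng(spec.seed)
    q = spec.latent_dim
    direction = np.zeros(q)
    direction[0] = 1.0
    if spec.trajectory == "branch":
        arm_a = np.zeros(q)
        arm_a[1] = 1.0
        arm_b = np.zeros(q)
        arm_b[1] = -1.0

    latent: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    times: list[np.ndarray] = []
    for n_b in spec.n_cells:
        lab = rng.integers(0, spec.n_clusters, size=n_b)
        t = lab + rng.uniform(0.0, 1.0, size=n_b)  # continuous latent time
        if spec.trajectory == "chain":
            pos = np.outer(t * spec.separation, direction)
        else:
            # first cluster is the trunk; remaining clusters alternate arms
            pos = np.zeros((n_b, q))
            trunk = lab == 0
            pos[trunk] = np.outer(t[trunk] * spec.separation, direction)
            for c in range(1, spec.n_clusters):
                rows = lab == c
                arm = arm_a if c % 2 == 1 else arm_b
                base_pt = direction * spec.separation  # end of the trunk
                pos[rows] = base_pt + np.outer(
                    (t[rows] - 1.0) * spec.separation, arm
                )
        pos = pos + rng.normal(0.0, spec.within_sd, size=(n_b, q))
        latent.append(pos)
        labels.append(lab)
        times.append(t)

    bundle, markers = _assemble(spec, latent, labels, rng)
    truth = SyntheticTruth(
        labels=np.concatenate(labels),
        batch=bundle.batch_labels(),
        time=np.concatenate(times),
        markers=markers,
        batch_unique={},
    )
    return bundle, truth


def write_truth(truth: SyntheticTruth, bundle: ExpressionBundle, out_dir) -> None:
    """Write ground-truth tables (labels, batch, time) as TSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = bundle.cell_ids()
    pd.DataFrame({"cell_id": cells, "label": truth.labels}).to_csv(
        out / "truth_labels.tsv", sep="\t", index=False, header=False
    )
    pd.DataFrame({"cell_id": cells, "batch": truth.batch}).to_csv(
        out / "truth_batch.tsv", sep="\t", index=False, header=False
    )
    if truth.time is not None:
        pd.DataFrame({"cell_id": cells, "time": truth.time}).to_csv(
            out / "truth_time.tsv", sep="\t", index=False, header=False
        )
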