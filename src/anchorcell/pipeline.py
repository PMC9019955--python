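"""End-to-end orchestration: normalize -> reduce -> ghosts -> encode -> smooth.

`integrate` is the canonical entry point producing the sparse embedding from
an aligned multi-batch bundle; `run_integrate` / `run_downstream` drive the
same steps from a file-based :class:`RunConfig` and write TSV/JSON outputs
plus a manifest, which is what the command-line interface wraps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .downstream import ClusterResult, cluster_cells, differential_genes
from .ghosts import default_m, find_ghost_cells
from .graph import build_sparse_encoding
from .io import (
    ExpressionBundle,
    NormalizedMatrix,
    align_common_genes,
    log_normalize,
    read_expression,
    read_labels,
)
from .lineage import (
    cluster_similarity_matrix,
    compute_pseudotime,
    infer_trajectory,
    select_root_cell,
)
from .message import Embedding, message_pass
from .metrics import evaluate_clustering
from .reduction import default_dim, reduce


@dataclass
class IntegrationResult:
    embedding: Embedding
    normalized: NormalizedMatrix
    reduced: Any
    ghosts: Any
    encoding: Any
    bundle: ExpressionBundle


def integrate(
    bundle: ExpressionBundle,
    d: int | None = None,
    m: int | list[int] | None = None,
    p: float = 0.3,
    method: str = "fsm",
    seed: int = 0,
) -> IntegrationResult:
    """Run the full sparse-encoding pipeline on an aligned bundle.

    Hyperparameters default to the package recommendations: d ~ M/100 in
    [30, 150], m ~ N_h/100 in [20, 100] per batch, p = 0.3.
    """
    norm = log_normalize(bundle)
    if d is None:
        d = default_dim(norm.M, norm.N)
    red = reduce(norm.values, d, method=method, seed=seed)
    if m is None:
        m = [default_m(n) for n in bundle.N_h]
    ghosts = find_ghost_cells(red.values, bundle.N_h, m, seed=seed)
    enc = build_sparse_encoding(red.values, ghosts, p=p)
    emb = message_pass(enc)
    return IntegrationResult(
        embedding=emb,
        normalized=norm,
        reduced=red,
        ghosts=ghosts,
        encoding=enc,
        bundle=bundle,
    )


@dataclass
class RunConfig:
    """File-based pipeline configuration (YAML-friendly)."""

    inputs: list[dict[str, str]] = field(default_factory=list)
    # each: {path, format?, batch_id, orientation?}
    out_dir: str = "anchorcell_out"
    d: int | None = None
    m: int | None = None
    p: float = 0.3
    k: int | None = None
    reduce_method: str = "fsm"
    seed: int = 0
    root_cluster: int | str = "auto"
    top_k: int = 20
    labels_path: str | None = None
    batch_path: str | None = None

    def warn_ranges(self) -> list[str]:
        notes = []
        if self.d is not None and not (30 <= self.d <= 150):
            notes.append(f"d={self.d} outside the recommended range [30, 150]")
        if self.m is not None and not (20 <= self.m <= 100):
            notes.append(f"m={self.m} outside the recommended range [20, 100]")
        return notes


def _load_bundle(config: RunConfig) -> ExpressionBundle:
    bundles = []
    for spec in config.inputs:
        bundles.append(
            read_expression(
                spec["path"],
                format=spec.get("format"),
                batch_id=spec.get("batch_id", f"batch{len(bundles)}"),
                orientation=spec.get("orientation", "cells-rows"),
                genes_path=spec.get("genes_path"),
                barcodes_path=spec.get("barcodes_path"),
            )
        )
    return align_common_genes(bundles)


def _write_manifest(out: Path, config: RunConfig, extra: dict) -> None:
    manifest = {
        "anchorcell_version": __version__,
        "seed": config.seed,
        "d": config.d,
        "m": config.m,
        "p": config.p,
        "k": config.k,
        "reduce_method": config.reduce_method,
        "warnings": config.warn_ranges(),
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_integrate(config: RunConfig) -> IntegrationResult:
    """Execute the pipeline from files and write Z_norm + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = _load_bundle(config)
    res = integrate(
        bundle,
        d=config.d,
        m=config.m,
        p=config.p,
        method=config.reduce_method,
        seed=config.seed,
    )
    df = pd.DataFrame(res.embedding.Z_norm, index=bundle.cell_ids())
    df.to_csv(out / "Z_norm.tsv", sep="\t", header=False)
    _write_manifest(
        out,
        config,
        {"n_cells": bundle.N, "n_genes": bundle.M, "n_batches": bundle.H},
    )
    return res


def _read_znorm(out: Path) -> tuple[np.ndarray, list[str]]:
    path = out / "Z_norm.tsv"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: run the integrate step first"
        )
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def run_downstream(config: RunConfig, task: str) -> dict[str, Any]:
    """Dispatch a downstream task on a previously written embedding."""
    out = Path(config.out_dir)
    if task == "cluster":
        Z, cells = _read_znorm(out)
        k = config.k or 8
        cl = cluster_cells(Z, k, seed=config.seed)
        pd.DataFrame({"cell_id": cells, "cluster": cl.labels}).to_csv(
            out / "clusters.tsv", sep="\t", index=False, header=False
        )
        return {"labels": cl.labels, "cells": cells}
    if task == "de":
        Z, cells = _read_znorm(out)
        cl_path = out / "clusters.tsv"
        if not cl_path.exists():
            raise FileNotFoundError(
                "clusters.tsv not found: run the cluster task before de"
            )
        lab = pd.read_csv(cl_path, sep="\t", header=None, index_col=0)[1]
        bundle = _load_bundle(config)
        norm = log_normalize(bundle)
        de = differential_genes(
            norm.values, lab.to_numpy(), gene_ids=norm.gene_ids, top_k=config.top_k
        )
        for c, table in de.tables.items():
            table.to_csv(out / f"de_cluster{c}.tsv", sep="\t", index=False)
        return {"de": de}
    if task == "trajectory":
        Z, cells = _read_znorm(out)
        cl_path = out / "clusters.tsv"
        if not cl_path.exists():
            raise FileNotFoundError(
                "clusters.tsv not found: run the cluster task before trajectory"
            )
        lab = pd.read_csv(cl_path, sep="\t", header=None, index_col=0)[1].to_numpy()
        A = cluster_similarity_matrix(Z, lab)
        tree = infer_trajectory(A, config.root_cluster)
        r1 = select_root_cell(Z, lab, tree)
        pt = compute_pseudotime(Z, lab, tree, r1)
        edges = pd.DataFrame(
            [
                (tree.parent[child], child, A[tree.parent[child], child])
                for child in tree.order
                if tree.parent[child] is not None
            ],
            columns=["parent", "child", "similarity"],
        )
        edges.to_csv(out / "trajectory_edges.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"cell_id": cells, "cluster": lab, "D": pt.D, "D_norm": pt.D_norm}
        ).to_csv(out / "pseudotime.tsv", sep="\t", index=False)
        return {"tree": tree, "pseudotime": pt}
    if task == "evaluate":
        cl_path = out / "clusters.tsv"
        if not cl_path.exists():
            raise FileNotFoundError(
                "clusters.tsv not found: run the cluster task before evaluate"
            )
        pred = pd.read_csv(cl_path, sep="\t", header=None, index_col=0)[1]
        if config.labels_path is None:
            raise ValueError("evaluate requires labels_path (truth labels TSV)")
        truth = read_labels(config.labels_path).reindex(pred.index)
        batch = (
            read_labels(config.batch_path).reindex(pred.index).to_numpy()
            if config.batch_path
            else None
        )
        report = evaluate_clustering(pred.to_numpy(), truth.to_numpy(), batch)
        (out / "evaluation.json").write_text(json.dumps(report, indent=2) + "\n")
        return report
    raise ValueError(f"unknown downstream task {task!r}")


def tune(
    bundle: ExpressionBundle,
    truth_labels: np.ndarray,
    d_grid: list[int],
    m_grid: list[int],
    p_grid: list[float],
    k: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid-search d, m, p by clustering NMI against provided labels."""
    from .metrics import nmi as _nmi

    rows = []
    for d in d_grid:
        for m in m_grid:
            for p in p_grid:
                res = integrate(bundle, d=d, m=m, p=p, seed=seed)
                cl = cluster_cells(res.embedding.Z_norm, k, seed=seed)
                rows.append(
                    {"d": d, "m": m, "p": p, "nmi": _nmi(cl.labels, truth_labels)}
                )
    return pd.DataFrame(rows).sort_values("nmi", ascending=False).reset_index(
        drop=True
    )
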