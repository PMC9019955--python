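"""Reading, writing, gene alignment and normalization of expression matrices.

Counts are handled as cells-by-genes matrices, one per batch.  Before any
embedding step the batches are restricted to their common genes (in a single
canonical order) and each entry is log10(1+r) transformed, then every gene
column is scaled by the square root of its *within-batch* column sum.  The
per-batch scaling keeps the normalization local to each dataset, so a batch
with deeper sequencing does not dominate the shared feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class ExpressionError(ValueError):
    """Raised for malformed or inconsistent expression inputs."""


@dataclass
class Batch:
    """One dataset: a cells-by-genes count matrix with identifiers."""

    matrix: np.ndarray  # cells x genes, non-negative
    cell_ids: list[str]
    batch_id: str

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ExpressionBundle:
    """One or more batches sharing a common, ordered gene set.

    Attributes
    ----------
    batches
        Per-batch matrices and identifiers.  After :func:`align_common_genes`
        every matrix has the same gene count and ordering.
    gene_ids
        Gene identifiers shared across batches, in matrix column order.
    """

    batches: list[Batch]
    gene_ids: list[str]

    @property
    def H(self) -> int:
        return len(self.batches)

    @property
    def M(self) -> int:
        return len(self.gene_ids)

    @property
    def N_h(self) -> list[int]:
        return [b.n_cells for b in self.batches]

    @property
    def N(self) -> int:
        return sum(self.N_h)

    @property
    def batch_ids(self) -> list[str]:
        return [b.batch_id for b in self.batches]

    def cell_ids(self) -> list[str]:
        out: list[str] = []
        for b in self.batches:
            out.extend(b.cell_ids)
        return out

    def batch_labels(self) -> np.ndarray:
        """Per-cell batch id, concatenated in batch order."""
        return np.array(
            [b.batch_id for b in self.batches for _ in range(b.n_cells)]
        )

    def validate(self) -> None:
        ids = self.batch_ids
        if len(set(ids)) != len(ids):
            raise ExpressionError("batch_ids must be unique across batches")
        for b in self.batches:
            if b.matrix.ndim != 2 or b.matrix.shape[1] != self.M:
                raise ExpressionError(
                    f"batch {b.batch_id!r}: matrix shape {b.matrix.shape} "
                    f"does not match {self.M} genes"
                )
            if len(b.cell_ids) != b.n_cells:
                raise ExpressionError(
                    f"batch {b.batch_id!r}: {len(b.cell_ids)} cell ids for "
                    f"{b.n_cells} rows"
                )
            if len(set(b.cell_ids)) != len(b.cell_ids):
                raise ExpressionError(
                    f"batch {b.batch_id!r}: duplicate cell ids"
                )
            if not np.all(np.isfinite(b.matrix)):
                raise ExpressionError(
                    f"batch {b.batch_id!r}: non-finite entries"
                )
            if b.matrix.size and b.matrix.min() < 0:
                raise ExpressionError(
                    f"batch {b.batch_id!r}: negative entries"
                )


@dataclass
class NormalizedMatrix:
    """Log-transformed, per-batch column-scaled expression (cells x genes)."""

    values: np.ndarray  # N x M
    gene_ids: list[str]
    cell_ids: list[str]
    batch_slices: list[slice]
    batch_ids: list[str] = field(default_factory=list)

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]


def _dedupe_genes(gene_ids: list[str]) -> tuple[list[str], np.ndarray]:
    """Keep the first occurrence of each gene id; warn on duplicates."""
    seen: dict[str, int] = {}
    keep: list[int] = []
    for idx, g in enumerate(gene_ids):
        if g in seen:
            continue
        seen[g] = idx
        keep.append(idx)
    if len(keep) != len(gene_ids):
        warnings.warn(
            f"{len(gene_ids) - len(keep)} duplicate gene ids dropped "
            "(first occurrence kept)",
            stacklevel=3,
        )
    kept_idx = np.array(keep, dtype=int)
    return [gene_ids[i] for i in keep], kept_idx


def _read_id_column(path: Path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_expression(
    path: str | Path,
    format: str | None = None,
    batch_id: str = "batch0",
    orientation: str = "cells-rows",
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> ExpressionBundle:
    """Read a single-batch count matrix from MTX or a dense CSV/TSV.

    MTX files need ``genes.tsv`` and ``barcodes.tsv`` sidecars (defaulting
    to those names next to the matrix).  ``orientation`` declares whether
    rows are cells or genes; genes-in-rows inputs are transposed.
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionError(f"input file not found: {path}")
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(
            path.suffix, "csv"
        )
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001 - surface parse location
            raise ExpressionError(f"malformed MTX file {path}: {exc}") from exc
        mat = np.asarray(sp.coo_matrix(mat).todense(), dtype=float)
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = (
            Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        )
        if not genes_path.exists() or not barcodes_path.exists():
            raise ExpressionError(
                f"MTX input {path} requires gene and barcode sidecar files"
            )
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(barcodes_path)
        if orientation == "genes-rows":
            mat = mat.T
        if mat.shape[1] != len(gene_ids):
            raise ExpressionError(
                f"matrix has {mat.shape[1]} gene columns but sidecar lists "
                f"{len(gene_ids)} genes"
            )
        if mat.shape[0] != len(cell_ids):
            raise ExpressionError(
                f"matrix has {mat.shape[0]} cell rows but sidecar lists "
                f"{len(cell_ids)} barcodes"
            )
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise ExpressionError(f"malformed {format} file {path}: {exc}") from exc
        if orientation == "genes-rows":
            df = df.T
        mat = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.columns]
        cell_ids = [str(c) for c in df.index]
    else:
        raise ExpressionError(f"unknown format {format!r}")

    if mat.size and mat.min() < 0:
        raise ExpressionError(f"negative entries in {path}")
    gene_ids, keep = _dedupe_genes(gene_ids)
    mat = mat[:, keep]
    bundle = ExpressionBundle(
        batches=[Batch(matrix=mat, cell_ids=cell_ids, batch_id=batch_id)],
        gene_ids=gene_ids,
    )
    bundle.validate()
    return bundle


def write_expression(bundle: ExpressionBundle, out_dir: str | Path) -> None:
    """Write each batch as MTX + genes.tsv/barcodes.tsv under ``out_dir``.

    Integer counts round-trip bit-exactly through the MTX integer format.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for b in bundle.batches:
        bdir = out_dir / b.batch_id
        bdir.mkdir(exist_ok=True)
        mat = sp.coo_matrix(b.matrix)
        is_int = np.allclose(b.matrix, np.round(b.matrix))
        scipy.io.mmwrite(
            bdir / "matrix.mtx",
            mat.astype(int) if is_int else mat,
            field="integer" if is_int else "real",
        )
        (bdir / "genes.tsv").write_text("\n".join(bundle.gene_ids) + "\n")
        (bdir / "barcodes.tsv").write_text("\n".join(b.cell_ids) + "\n")


def read_labels(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (cell_id, label) into a Series indexed by cell."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"])
    return df.set_index("cell_id")["label"]


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", header=False)


def align_common_genes(bundles: list[ExpressionBundle]) -> ExpressionBundle:
    """Restrict every batch to the shared genes, lexicographically ordered.

    The intersection of gene ids across all input bundles defines the common
    gene set; an empty intersection is an error because the encoding requires
    genes aligned and shared across all the datasets.
    """
    if not bundles:
        raise ExpressionError("need at least one bundle")
    common = set(bundles[0].gene_ids)
    for b in bundles[1:]:
        common &= set(b.gene_ids)
    if not common:
        raise ExpressionError(
            "no genes are shared across all batches; integration requires a "
            "non-empty common gene set"
        )
    order = sorted(common)
    batches: list[Batch] = []
    for bundle in bundles:
        pos = {g: i for i, g in enumerate(bundle.gene_ids)}
        idx = np.array([pos[g] for g in order], dtype=int)
        for b in bundle.batches:
            batches.append(
                Batch(
                    matrix=b.matrix[:, idx],
                    cell_ids=list(b.cell_ids),
                    batch_id=b.batch_id,
                )
            )
    out = ExpressionBundle(batches=batches, gene_ids=order)
    out.validate()
    return out


def log_normalize(bundle: ExpressionBundle) -> NormalizedMatrix:
    """Log-transform counts and scale columns by their within-batch sums.

    Each entry becomes ``log10(r + 1)``, then within each batch every gene
    column is divided by the square root of its column sum of the
    log-transformed values.  All-zero columns stay zero (0/0 := 0).
    """
    bundle.validate()
    blocks: list[np.ndarray] = []
    slices: list[slice] = []
    start = 0
    for b in bundle.batches:
        r = np.log10(b.matrix + 1.0)
        colsum = r.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(colsum > 0, r / np.sqrt(colsum), 0.0)
        blocks.append(x)
        slices.append(slice(start, start + b.n_cells))
        start += b.n_cells
    return NormalizedMatrix(
        values=np.vstack(blocks) if blocks else np.empty((0, bundle.M)),
        gene_ids=list(bundle.gene_ids),
        cell_ids=bundle.cell_ids(),
        batch_slices=slices,
        batch_ids=bundle.batch_ids,
    )
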