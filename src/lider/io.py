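"""Reading and writing expression matrices, labels, embeddings and predictions.

The in-memory convention is cells x genes everywhere: ``values[i, j]`` is the
expression of gene ``gene_ids[j]`` in cell ``cell_ids[i]``. Readers normalise
on-disk orientation to this layout at load time. Supported formats are dense
TSV/CSV (one header row of gene ids, one leading column of cell ids, or the
transpose) and the 10x-style Matrix Market triplet (``matrix.mtx`` with
``genes.tsv`` and ``barcodes.tsv`` sidecars).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import (
    AlignmentError,
    DimensionError,
    DuplicateKeyError,
    FormatError,
    ParseError,
)

__all__ = [
    "ExpressionMatrix",
    "LabelSet",
    "AlignmentReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_cell_labels",
    "write_cell_labels",
    "align_genes",
    "write_predictions",
    "read_predictions",
    "write_embeddings",
]


@dataclass
class ExpressionMatrix:
    """A cells x genes real matrix with identifiers.

    Parameters
    ----------
    values
        Array of shape ``(n_cells, n_genes)``; must be finite.
    gene_ids, cell_ids
        Ordered, unique identifiers for columns and rows.
    standardized
        Whether the values have already been z-scored per gene.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n, d = self.values.shape
        if n != len(self.cell_ids):
            raise DimensionError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if d != len(self.gene_ids):
            raise DimensionError(
                f"matrix has {d} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != d:
            raise DuplicateKeyError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise DuplicateKeyError("cell_ids are not unique")
        if not np.isfinite(self.values).all():
            raise ParseError("expression matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelSet:
    """Per-cell type labels, in file order."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = [str(l).strip() for l in self.labels]
        if len(self.cell_ids) != len(self.labels):
            raise DimensionError("cell_ids and labels differ in length")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DuplicateKeyError("duplicate cell id in label set")
        if any(l == "" for l in self.labels):
            raise ParseError("empty label encountered")

    def __len__(self) -> int:
        return len(self.cell_ids)


@dataclass
class AlignmentReport:
    """Bookkeeping from :func:`align_genes`."""

    n_reference: int
    n_target: int
    n_matched: int
    filled_genes: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)


def _delimiter_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_matrix(
    path: str,
    format: str = "dense_tsv",
    orientation: str = "cells_by_genes",
) -> ExpressionMatrix:
    """Read an expression matrix, normalising to cells x genes.

    ``format`` is one of ``dense_tsv``, ``dense_csv`` or ``mtx_triplet``;
    ``orientation`` describes the on-disk layout. Matrix Market triplets are
    densified on load and expect ``genes.tsv`` / ``barcodes.tsv`` next to the
    triplet file, listing the row-axis and column-axis identifiers for a
    genes-by-cells file (10x convention).
    """
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if format in ("dense_tsv", "dense_csv"):
        mat = _read_dense(path, _delimiter_for(path) if format == "dense_tsv" else ",")
    elif format == "mtx_triplet":
        mat = _read_mtx_triplet(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if orientation == "genes_by_cells":
        mat = ExpressionMatrix(
            values=mat.values.T,
            gene_ids=mat.cell_ids,  # axis labels swap with the transpose
            cell_ids=mat.gene_ids,
        )
    return mat


def _read_dense(path: str, sep: str) -> ExpressionMatrix:
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, header=0, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: header row defines no data columns")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]
    ]
    if len(non_numeric) > 0:
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ParseError(
            f"{path}: non-numeric value at row {row!r}, column {col!r}"
        )
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        gene_ids=list(df.columns),
        cell_ids=list(df.index),
    )


def _read_sidecar(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _read_mtx_triplet(path: str) -> ExpressionMatrix:
    directory = os.path.dirname(os.path.abspath(path))
    genes_path = os.path.join(directory, "genes.tsv")
    barcodes_path = os.path.join(directory, "barcodes.tsv")
    for sidecar in (genes_path, barcodes_path):
        if not os.path.exists(sidecar):
            raise FormatError(f"missing sidecar file {sidecar}")
    try:
        sparse = scipy.io.mmread(path)
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    dense = np.asarray(
        sparse.todense() if scipy.sparse.issparse(sparse) else sparse,
        dtype=np.float64,
    )
    genes = _read_sidecar(genes_path)
    barcodes = _read_sidecar(barcodes_path)
    n_rows, n_cols = dense.shape
    if len(genes) != n_rows:
        raise DimensionError(
            f"{path}: matrix declares {n_rows} rows but genes.tsv lists {len(genes)}"
        )
    if len(barcodes) != n_cols:
        raise DimensionError(
            f"{path}: matrix declares {n_cols} columns but barcodes.tsv lists {len(barcodes)}"
        )
    # MTX triplets follow the 10x genes-by-cells layout; the caller's
    # orientation flag is applied on top of this by read_expression_matrix,
    # so here we return the on-disk axes verbatim as a cells_by_genes view
    # with rows=genes labelled accordingly.
    return ExpressionMatrix(values=dense, gene_ids=barcodes, cell_ids=genes)


def write_expression_matrix(matrix: ExpressionMatrix, path: str) -> None:
    """Write a dense TSV/CSV (delimiter from extension) in cells x genes."""
    df = pd.DataFrame(matrix.values, index=matrix.cell_ids, columns=matrix.gene_ids)
    df.index.name = "cell_id"
    df.to_csv(path, sep=_delimiter_for(path), float_format="%.17g")


def read_cell_labels(path: str) -> LabelSet:
    """Read a two-column (cell_id, label) delimited file with a header."""
    df = pd.read_csv(path, sep=None, engine="python", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (cell_id, label)")
    cell_ids = df.iloc[:, 0].tolist()
    labels = df.iloc[:, 1].tolist()
    if any(pd.isna(l) for l in labels):
        row = next(i for i, l in enumerate(labels) if pd.isna(l))
        raise ParseError(f"{path}: missing label at data row {row}")
    if len(set(cell_ids)) != len(cell_ids):
        seen: set[str] = set()
        dup = next(c for c in cell_ids if c in seen or seen.add(c))
        raise DuplicateKeyError(f"{path}: duplicate cell id {dup!r}")
    return LabelSet(cell_ids=cell_ids, labels=labels)


def write_cell_labels(labels: LabelSet, path: str) -> None:
    pd.DataFrame({"cell_id": labels.cell_ids, "label": labels.labels}).to_csv(
        path, sep=_delimiter_for(path), index=False
    )


def align_genes(
    reference_genes: list[str],
    target: ExpressionMatrix,
    fill_value: float = 0.0,
) -> tuple[ExpressionMatrix, AlignmentReport]:
    """Project ``target`` onto ``reference_genes`` in reference order.

    Genes absent from the target are filled with ``fill_value`` (0 is the
    per-gene mean on the z-scored scale); target genes not in the reference
    are dropped. Raises :class:`AlignmentError` when no genes overlap.
    """
    reference_genes = [str(g) for g in reference_genes]
    if len(set(reference_genes)) != len(reference_genes):
        raise DuplicateKeyError("reference gene list is not unique")
    target_index = {g: j for j, g in enumerate(target.gene_ids)}
    matched = [g for g in reference_genes if g in target_index]
    if not matched:
        raise AlignmentError(
            "no overlapping genes between reference and target; "
            "the datasets appear incompatible"
        )
    out = np.full((target.n_cells, len(reference_genes)), float(fill_value))
    for j, g in enumerate(reference_genes):
        if g in target_index:
            out[:, j] = target.values[:, target_index[g]]
    report = AlignmentReport(
        n_reference=len(reference_genes),
        n_target=target.n_genes,
        n_matched=len(matched),
        filled_genes=[g for g in reference_genes if g not in target_index],
        dropped_genes=[g for g in target.gene_ids if g not in set(reference_genes)],
    )
    aligned = ExpressionMatrix(
        values=out,
        gene_ids=list(reference_genes),
        cell_ids=list(target.cell_ids),
        standardized=target.standardized,
    )
    return aligned, report


def write_predictions(
    cell_ids: list[str],
    predicted_labels: list[str],
    probabilities: np.ndarray,
    class_names: list[str],
    path: str,
) -> None:
    """Write one row per cell: cell_id, predicted label, per-class probabilities."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if not (len(cell_ids) == len(predicted_labels) == probabilities.shape[0]):
        raise DimensionError("cell_ids, labels and probability rows differ in length")
    if probabilities.shape[1] != len(class_names):
        raise DimensionError("probability columns do not match class_names")
    sums = probabilities.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise DimensionError(
            f"probability row {bad} sums to {sums[bad]:.6f}, expected 1"
        )
    df = pd.DataFrame(probabilities, columns=class_names)
    df.insert(0, "predicted_label", predicted_labels)
    df.insert(0, "cell_id", cell_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path: str) -> tuple[list[str], list[str], np.ndarray, list[str]]:
    """Read back a predictions file: (cell_ids, labels, probabilities, class_names)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"cell_id": str})
    class_names = list(df.columns[2:])
    return (
        df["cell_id"].tolist(),
        df["predicted_label"].astype(str).tolist(),
        df[class_names].to_numpy(dtype=np.float64),
        class_names,
    )


def write_embeddings(cell_ids: list[str], values: np.ndarray, path: str) -> None:
    """Export an n x k embedding as dense TSV (cell_id + k value columns)."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[0] != len(cell_ids):
        raise DimensionError("embedding rows do not match cell ids")
    cols = [f"dim_{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=cell_ids, columns=cols)
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t", float_format="%.17g")
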