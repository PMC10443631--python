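"""Cohort data model and on-disk exchange formats.

A cohort is a sparse cells × genes UMI count matrix with two annotation
tables.  On disk the matrix is stored in Matrix Market coordinate format
(genes × cells, the common exchange convention) with tab-separated cell and
gene sidecars; the reader transposes to cells × genes internally and
recomputes the derived per-cell columns (``total_umi``, ``mito_fraction``)
rather than trusting the sidecar.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import file_sha256, logger

CONDITIONS = ("naive", "sham", "mcao")
TISSUE_CLASSES = ("bone", "meninges", "brain")

_CELL_COLUMNS = [
    "cell_id",
    "region",
    "condition",
    "cell_type",
    "sample_id",
    "tissue_class",
    "total_umi",
    "mito_fraction",
    "doublet_score",
]
_GENE_COLUMNS = ["gene_id", "is_mito"]

_ORIENTATION_FLAG = "#orientation="


class CohortValidationError(ValueError):
    """Structural problem in a cohort (dimension mismatch, bad values)."""

    def __init__(self, message: str, axis: str | None = None):
        super().__init__(message)
        self.axis = axis


@dataclasses.dataclass
class CellMatrix:
    """Sparse cells × genes UMI counts plus per-cell / per-gene annotations.

    ``counts`` is CSR with non-negative integer values; ``cells`` and
    ``genes`` are DataFrames aligned with the matrix rows and columns.
    ``total_umi`` and ``mito_fraction`` are derived columns and are always
    recomputed by :meth:`validate`.
    """

    counts: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def refresh_derived(self) -> None:
        """Recompute total_umi and mito_fraction from the count matrix."""
        total = np.asarray(self.counts.sum(axis=1)).ravel()
        is_mito = np.asarray(self.genes["is_mito"], dtype=bool)
        mito = np.asarray(self.counts[:, is_mito].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        self.cells = self.cells.copy()
        self.cells["total_umi"] = total.astype(np.int64)
        self.cells["mito_fraction"] = frac

    def validate(self) -> "CellMatrix":
        """Check all invariants; recompute derived columns. Returns self."""
        n, g = self.counts.shape
        if len(self.cells) != n:
            raise CohortValidationError(
                f"cell table has {len(self.cells)} rows but matrix has {n} cells",
                axis="cells",
            )
        if len(self.genes) != g:
            raise CohortValidationError(
                f"gene table has {len(self.genes)} rows but matrix has {g} genes",
                axis="genes",
            )
        for col in _CELL_COLUMNS:
            if col not in self.cells.columns and col not in ("total_umi", "mito_fraction"):
                raise CohortValidationError(f"cell table missing column {col!r}", axis="cells")
        for col in _GENE_COLUMNS:
            if col not in self.genes.columns:
                raise CohortValidationError(f"gene table missing column {col!r}", axis="genes")
        data = self.counts.data
        if data.size and (np.any(data < 0) or not np.allclose(data, np.round(data))):
            raise CohortValidationError("counts must be non-negative integers")
        self.counts = sp.csr_matrix(
            (np.asarray(np.round(data), dtype=np.int64), self.counts.indices, self.counts.indptr),
            shape=self.counts.shape,
        )
        if self.cells["cell_id"].duplicated().any():
            raise CohortValidationError("duplicate cell ids", axis="cells")
        if self.genes["gene_id"].duplicated().any():
            raise CohortValidationError("duplicate gene ids", axis="genes")
        self.refresh_derived()
        return self

    def subset(self, cell_idx=None, gene_idx=None) -> "CellMatrix":
        """Positional subset along either axis; derived columns refreshed."""
        counts = self.counts
        cells = self.cells
        genes = self.genes
        if cell_idx is not None:
            cell_idx = np.asarray(cell_idx)
            counts = counts[cell_idx]
            cells = cells.iloc[cell_idx].reset_index(drop=True)
        if gene_idx is not None:
            gene_idx = np.asarray(gene_idx)
            counts = counts[:, gene_idx]
            genes = genes.iloc[gene_idx].reset_index(drop=True)
        out = CellMatrix(sp.csr_matrix(counts), cells, genes)
        out.refresh_derived()
        return out

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells × genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cells.set_index("cell_id"),
            var=self.genes.set_index("gene_id"),
        )


@dataclasses.dataclass
class NormalizedLayer:
    """Log-normalized expression: values = ln(count / size_factor + 1)."""

    values: sp.csr_matrix  # cells x genes, float
    size_factors: np.ndarray
    gene_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class ResultTable:
    """A typed result table with declared key columns for stable ordering."""

    frame: pd.DataFrame
    key_columns: Sequence[str] = ()


def read_cohort(matrix_path, cells_path, genes_path) -> CellMatrix:
    """Read a cohort from Matrix Market + TSV sidecars and validate it.

    The cells sidecar may start with an ``#orientation=`` comment line
    declaring whether the matrix stores ``genes_x_cells`` (default) or
    ``cells_x_genes``.
    """
    orientation = "genes_x_cells"
    with open(cells_path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    skiprows = 0
    if first.startswith(_ORIENTATION_FLAG):
        orientation = first[len(_ORIENTATION_FLAG):].strip()
        skiprows = 1
    if orientation not in ("genes_x_cells", "cells_x_genes"):
        raise CohortValidationError(f"unknown matrix orientation {orientation!r}")
    cells = pd.read_csv(
        cells_path, sep="\t", skiprows=skiprows, na_values=["NA"],
        keep_default_na=False, float_precision="round_trip",
    )
    genes = pd.read_csv(genes_path, sep="\t", na_values=["NA"], keep_default_na=False)
    mat = scipy.io.mmread(os.fspath(matrix_path))
    if orientation == "genes_x_cells":
        mat = mat.T
    mat = sp.csr_matrix(mat)
    if mat.data.size and (np.any(mat.data < 0) or not np.allclose(mat.data, np.round(mat.data))):
        raise CohortValidationError("matrix contains negative or non-integer values")
    if "is_mito" in genes.columns:
        genes["is_mito"] = _parse_bool(genes["is_mito"])
    cohort = CellMatrix(mat, cells, genes)
    return cohort.validate()


def _parse_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.lower().isin(("true", "1", "t", "yes"))


def write_cohort(cohort: CellMatrix, out_dir) -> ResultTable:
    """Write matrix.mtx (genes × cells) + cells.tsv + genes.tsv + manifest.

    Returns the manifest: one row per emitted data file with its SHA-256
    checksum and dimensions.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    matrix_path = out_dir / "matrix.mtx"
    cells_path = out_dir / "cells.tsv"
    genes_path = out_dir / "genes.tsv"
    scipy.io.mmwrite(
        os.fspath(matrix_path), sp.coo_matrix(cohort.counts.T), field="integer"
    )
    cells = cohort.cells[_CELL_COLUMNS]
    with open(cells_path, "w", encoding="utf-8") as fh:
        fh.write(_ORIENTATION_FLAG + "genes_x_cells\n")
        cells.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    cohort.genes[_GENE_COLUMNS].to_csv(genes_path, sep="\t", index=False)
    rows = []
    for name, path, (nr, nc) in [
        ("matrix.mtx", matrix_path, (cohort.n_genes, cohort.n_cells)),
        ("cells.tsv", cells_path, (cohort.n_cells, len(_CELL_COLUMNS))),
        ("genes.tsv", genes_path, (cohort.n_genes, len(_GENE_COLUMNS))),
    ]:
        rows.append({"file": name, "sha256": file_sha256(path), "n_rows": nr, "n_cols": nc})
    manifest = ResultTable(pd.DataFrame(rows), key_columns=("file",))
    write_result(manifest, out_dir / "manifest.tsv")
    return manifest


def write_result(table: ResultTable, out_path) -> None:
    """Write a result table as TSV: floats at 17 significant digits (lossless
    round trip), NaN rendered as ``NA``, rows sorted by the key columns."""
    frame = table.frame
    if len(table.key_columns):
        keys = list(table.key_columns)
        if frame.duplicated(subset=keys).any():
            raise ValueError(f"duplicate rows for key columns {keys}")
        frame = frame.sort_values(keys, kind="mergesort").reset_index(drop=True)
    out_path = Path(out_path)
    try:
        frame.to_csv(
            out_path, sep="\t", index=False, float_format="%.17g", na_rep="NA"
        )
    except OSError as exc:
        raise IOError(f"cannot write result table to {out_path}: {exc}") from exc


def read_result(path, key_columns: Sequence[str] = ()) -> ResultTable:
    frame = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
    return ResultTable(frame, key_columns=tuple(key_columns))


def infer_tissue_class(region: str) -> str:
    """Map a region label to its tissue class (meninges/brain/bone)."""
    r = region.lower()
    if r in ("meninges", "dura"):
        return "meninges"
    if r == "brain":
        return "brain"
    return "bone"
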