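"""Reading and writing of single-cell expression matrices and cell metadata.

The canonical in-memory orientation is genes x cells, matching the usual
convention for 10x-style Matrix Market triplets. All downstream modules
consume only the in-memory containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Malformed on-disk input (bad header, ragged rows, dimension mismatch)."""


class ValidationError(ValueError):
    """Input parsed but violates a contract (negative counts, duplicate ids)."""


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with ordered identifiers.

    ``values`` holds raw counts unless ``normalized`` is set, in which case
    entries are real-valued (e.g. min-max scaled to [0, 1]).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-d matrix")
        p, n = self.values.shape
        if p != len(self.gene_ids) or n != len(self.cell_ids):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != p:
            raise ValidationError("gene_ids contain duplicates")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids contain duplicates")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("expression values must be nonnegative")
        if not self.normalized and self.values.size:
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("raw counts must be integers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` in the given order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:5]}...")
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[rows, :], list(gene_ids), list(self.cell_ids), self.normalized
        )

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in cell_ids]
        return ExpressionMatrix(
            self.values[:, cols], list(self.gene_ids), list(cell_ids), self.normalized
        )


@dataclass
class CellMetadata:
    """Per-cell annotations: timepoint, optional strata and type labels."""

    cell_ids: list[str]
    timepoint: list = field(default_factory=list)
    strata: list | None = None
    labels: list | None = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        n = len(self.cell_ids)
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell_id in metadata")
        for name in ("timepoint", "strata", "labels"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValidationError(f"{name} length {len(v)} != {n} cells")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def reorder(self, cell_ids: Sequence[str]) -> "CellMetadata":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in idx]
        if missing:
            raise ValidationError(
                f"{len(missing)} cells in matrix absent from metadata "
                f"(e.g. {missing[:3]})"
            )
        order = [idx[c] for c in cell_ids]

        def take(v):
            return None if v is None else [v[i] for i in order]

        return CellMetadata(
            list(cell_ids), take(self.timepoint), take(self.strata), take(self.labels)
        )


@dataclass
class TimepointDataset:
    """An expression matrix and its cell metadata, aligned on cell order."""

    matrix: ExpressionMatrix
    meta: CellMetadata

    def __post_init__(self) -> None:
        if self.matrix.cell_ids != self.meta.cell_ids:
            # Reorder metadata to the matrix order; any cell in the matrix
            # missing from the metadata is a hard error (no silent drop).
            self.meta = self.meta.reorder(self.matrix.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    @property
    def labels(self) -> list | None:
        return self.meta.labels


def _read_lines(path) -> list[str]:
    # pandas transparently handles .gz; features files may have 1-3 columns
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df


def read_mtx_triplet(matrix_path, features_path, barcodes_path) -> ExpressionMatrix:
    """Read a 10x-style triplet (matrix.mtx + features.tsv + barcodes.tsv).

    The features TSV may have 1-3 columns (v2/v3 dialects); the first column
    is taken as the gene identifier. Returns a dense genes x cells matrix.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    features = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    p, n = mat.shape
    if len(features) != p:
        raise FormatError(
            f"MTX header declares {p} genes but features file has {len(features)} lines"
        )
    if len(barcodes) != n:
        raise FormatError(
            f"MTX header declares {n} cells but barcodes file has {len(barcodes)} lines"
        )
    dense = np.asarray(mat.todense())
    if dense.size and dense.min() < 0:
        raise ValidationError("negative entries in count matrix")
    if not np.allclose(dense, np.round(dense)):
        raise ValidationError("non-integer entries in count matrix")
    return ExpressionMatrix(
        dense.astype(np.int64),
        list(features.iloc[:, 0]),
        list(barcodes.iloc[:, 0]),
        normalized=False,
    )


def write_mtx_triplet(m: ExpressionMatrix, matrix_path, features_path, barcodes_path) -> None:
    """Write a triplet readable by :func:`read_mtx_triplet` (integer field)."""
    if m.normalized:
        raise ValidationError("MTX triplet output is defined for raw counts only")
    sp = scipy.sparse.coo_matrix(m.values.astype(np.int64))
    scipy.io.mmwrite(str(matrix_path), sp, field="integer")
    pd.DataFrame({0: m.gene_ids}).to_csv(features_path, sep="\t", header=False, index=False)
    pd.DataFrame({0: m.cell_ids}).to_csv(barcodes_path, sep="\t", header=False, index=False)


def read_csv_matrix(path, genes_in_rows: bool = True) -> ExpressionMatrix:
    """Read a dense CSV with a header row and a row-name column."""
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed CSV {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValidationError(f"missing values in matrix CSV {path}")
    if not genes_in_rows:
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"non-numeric entries in matrix CSV {path}")
    return ExpressionMatrix(
        values, [str(i) for i in df.index], [str(c) for c in df.columns], normalized=False
    )


def write_csv_matrix(m: ExpressionMatrix, path, genes_in_rows: bool = True) -> None:
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
    if not genes_in_rows:
        df = df.T
    df.to_csv(path)


_REQUIRED_META_COLS = ("cell_id", "timepoint")


def read_metadata(path) -> CellMetadata:
    """Read a delimited cell metadata table (cell_id, timepoint[, strata, label])."""
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in _REQUIRED_META_COLS:
        if col not in df.columns:
            raise FormatError(f"metadata file {path} lacks required column '{col}'")
    if df["cell_id"].duplicated().any():
        dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate cell_id '{dup}' in metadata")
    return CellMetadata(
        cell_ids=list(df["cell_id"]),
        timepoint=list(df["timepoint"]),
        strata=list(df["strata"]) if "strata" in df.columns else None,
        labels=list(df["label"]) if "label" in df.columns else None,
    )


def write_metadata(meta: CellMetadata, path) -> None:
    cols = {"cell_id": meta.cell_ids, "timepoint": meta.timepoint}
    if meta.strata is not None:
        cols["strata"] = meta.strata
    if meta.labels is not None:
        cols["label"] = meta.labels
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
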