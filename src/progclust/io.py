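"""Expression matrix container, preprocessing filters and on-disk formats.

The whole package works on a single in-memory convention: a genes x cells
matrix of nonnegative values (raw UMI/read counts, or normalized expression
when flagged).  Readers accept 10x Genomics Matrix Market triplet directories
(both the v2 ``genes.tsv`` and v3 ``features.tsv`` dialects, plain or gzip)
and dense delimited tables in either orientation; everything downstream
assumes genes x cells.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class MatrixFormatError(ValueError):
    """A component file is missing, ill-formed, or inconsistent."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise MatrixFormatError(f"duplicate {what} ids: {', '.join(dups[:10])}")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense nonnegative array of shape ``(n_genes, n_cells)``.  Raw count
        matrices must be integer-valued.
    gene_ids, cell_ids
        Unique identifiers matching the two axes.
    is_normalized
        True when ``values`` holds normalized expression rather than counts.
        Downstream defaults (the rare-detection noise threshold in
        particular) depend on this flag.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise MatrixFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if self.values.size and self.values.min() < 0:
            raise MatrixFormatError("expression values must be nonnegative")
        if not self.is_normalized and self.values.size:
            if not np.allclose(self.values, np.round(self.values)):
                raise MatrixFormatError("count matrix contains non-integer values")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        """Column subset by integer or boolean index, order preserving."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionMatrix(
            self.values[:, index],
            self.gene_ids,
            [self.cell_ids[i] for i in index],
            self.is_normalized,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row subset by gene identifier, in the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        return ExpressionMatrix(
            self.values[idx, :], list(gene_ids), self.cell_ids, self.is_normalized
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


# ---------------------------------------------------------------------------
# 10x Matrix Market triplet directories
# ---------------------------------------------------------------------------

def _find_component(dir_path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = dir_path / (stem + suffix)
            if p.exists():
                return p
    raise MatrixFormatError(
        f"no {stems[0]!r}-like file found in {dir_path} (looked for {list(stems)})"
    )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_id_column(path: Path) -> list[str]:
    with _open_text(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    return [r[0] for r in rows]


def read_10x_mtx(dir_path: str | Path) -> ExpressionMatrix:
    """Read a 10x-style directory (matrix.mtx + genes/features + barcodes).

    Both the v2 dialect (``genes.tsv``, two columns) and the v3 dialect
    (``features.tsv``, three columns) are accepted; gzip is detected by
    extension.  Returns raw counts, genes x cells.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise MatrixFormatError(f"not a directory: {dir_path}")
    mtx_path = _find_component(dir_path, ["matrix.mtx"])
    genes_path = _find_component(dir_path, ["features.tsv", "genes.tsv"])
    barcodes_path = _find_component(dir_path, ["barcodes.tsv"])

    try:
        if mtx_path.suffix == ".gz":
            with gzip.open(mtx_path, "rb") as fh:
                mat = spio.mmread(fh)
        else:
            mat = spio.mmread(mtx_path)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise MatrixFormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sparse.coo_matrix(mat)

    gene_ids = _read_id_column(genes_path)
    cell_ids = _read_id_column(barcodes_path)
    if mat.shape[0] != len(gene_ids):
        raise MatrixFormatError(
            f"{mtx_path.name} has {mat.shape[0]} rows but "
            f"{genes_path.name} lists {len(gene_ids)} genes"
        )
    if mat.shape[1] != len(cell_ids):
        raise MatrixFormatError(
            f"{mtx_path.name} has {mat.shape[1]} columns but "
            f"{barcodes_path.name} lists {len(cell_ids)} barcodes"
        )
    if len(cell_ids) == 0:
        raise MatrixFormatError("no cells in matrix")
    values = np.asarray(mat.todense())
    if np.allclose(values, np.round(values)):
        values = np.round(values).astype(np.int64)
    return ExpressionMatrix(values, gene_ids, cell_ids, is_normalized=False)


def write_10x_mtx(m: ExpressionMatrix, dir_path: str | Path) -> None:
    """Write a plain-text v2-dialect 10x triplet directory."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    coo = sparse.coo_matrix(m.values)
    spio.mmwrite(dir_path / "matrix.mtx", coo, field="integer" if not m.is_normalized else "real")
    with open(dir_path / "genes.tsv", "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for c in m.cell_ids:
            fh.write(f"{c}\n")


# ---------------------------------------------------------------------------
# Dense delimited tables
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override:
        return override
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_csv_matrix(
    path: str | Path,
    orientation: str = "genes_by_cells",
    is_normalized: bool = False,
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a dense delimited matrix with row/column identifier headers.

    ``orientation`` names the layout of the *file*; the returned matrix is
    always genes x cells.
    """
    if orientation not in {"genes_by_cells", "cells_by_genes"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        # locate the first offending entry for the error message
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise MatrixFormatError(
                    f"non-numeric entry {df.iloc[i, j]!r} at row "
                    f"{df.index[i]!r}, column {col!r} in {path}"
                ) from exc
        raise
    if orientation == "cells_by_genes":
        values = values.T
        gene_ids, cell_ids = list(df.columns), list(df.index)
    else:
        gene_ids, cell_ids = list(df.index), list(df.columns)
    if not is_normalized and values.size and np.allclose(values, np.round(values)):
        values = np.round(values).astype(np.int64)
    return ExpressionMatrix(values, gene_ids, cell_ids, is_normalized=is_normalized)


def write_csv_matrix(
    m: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    m.to_frame().to_csv(path, sep=_sniff_delimiter(path, delimiter))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_cells_genes(
    m: ExpressionMatrix,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 2000,
) -> ExpressionMatrix:
    """Drop lowly covered genes, then sparsely covered cells.

    A gene is kept when it is expressed (strictly positive) in at least
    ``min_cells_per_gene`` cells; afterwards a cell is kept when it expresses
    at least ``min_genes_per_cell`` of the remaining genes.  Single pass each,
    genes first.
    """
    expressed = m.values > 0
    gene_keep = expressed.sum(axis=1) >= min_cells_per_gene
    if not gene_keep.any():
        raise ValueError(
            "all genes removed by the expression filter; "
            "relax min_cells_per_gene"
        )
    values = m.values[gene_keep, :]
    cell_keep = (values > 0).sum(axis=0) >= min_genes_per_cell
    if not cell_keep.any():
        raise ValueError(
            "all cells removed by the expressed-gene filter; "
            "relax min_genes_per_cell"
        )
    return ExpressionMatrix(
        values[:, cell_keep],
        [g for g, k in zip(m.gene_ids, gene_keep) if k],
        [c for c, k in zip(m.cell_ids, cell_keep) if k],
        m.is_normalized,
    )


# ---------------------------------------------------------------------------
# Final assignment table
# ---------------------------------------------------------------------------

@dataclass
class AssignmentRecord:
    label: str
    round: int
    node_path: list[int]
    is_rare: bool


@dataclass
class Assignment:
    """Flat cell -> cluster map with tree provenance.

    ``label`` is the canonical leaf name, ``round`` the clustering tree the
    cell ended in (1 = abundant, 2 = rare), ``node_path`` the child-index
    path to the leaf within that tree.
    """

    records: dict[str, AssignmentRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def labels(self) -> dict[str, str]:
        return {c: r.label for c, r in self.records.items()}

    def rare_cells(self) -> list[str]:
        return [c for c, r in self.records.items() if r.is_rare]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c,
                "label": r.label,
                "round": r.round,
                "node_path": "/".join(str(i) for i in r.node_path),
                "is_rare": r.is_rare,
            }
            for c, r in self.records.items()
        ]
        return pd.DataFrame(
            rows, columns=["cell_id", "label", "round", "node_path", "is_rare"]
        )


def write_assignment(a: Assignment, path: str | Path) -> None:
    """Write the assignment as a TSV, one row per cell, input cell order."""
    a.to_frame().to_csv(path, sep="\t", index=False)


def read_assignment(path: str | Path) -> Assignment:
    df = pd.read_csv(path, sep="\t", dtype={"node_path": str})
    records: dict[str, AssignmentRecord] = {}
    for _, row in df.iterrows():
        path_str = row["node_path"]
        node_path = (
            [int(x) for x in str(path_str).split("/")]
            if isinstance(path_str, str) and path_str != "" and path_str != "nan"
            else []
        )
        records[str(row["cell_id"])] = AssignmentRecord(
            label=str(row["label"]),
            round=int(row["round"]),
            node_path=node_path,
            is_rare=bool(row["is_rare"]),
        )
    return Assignment(records)
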