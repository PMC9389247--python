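"""Readers and writers for the on-disk formats the pipeline touches.

Two formats carry all primary data: 10x-style Matrix Market directories
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``) for UMI count
matrices, and GMT for gene-set collections.  Matrix Market indices are
1-based on disk and converted to 0-based in memory.  Matrices are stored
cells x genes internally; the genes-in-rows dialect is transposed on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "FormatError",
    "CountMatrix",
    "GeneSetCollection",
    "read_mtx_dir",
    "write_mtx_dir",
    "read_gmt",
    "write_gmt",
]

TOOL_TAG = "embrisk 0.1.0"


class FormatError(ValueError):
    """An on-disk file violates its format contract."""


def _as_str_array(values) -> np.ndarray:
    return np.asarray(list(values), dtype=object)


@dataclass
class CountMatrix:
    """Sparse cells x genes UMI count matrix with identifiers.

    Attributes
    ----------
    values : scipy.sparse.csr_matrix
        Non-negative integer counts, one row per cell.
    barcodes : ndarray of str
        Unique cell barcodes (row labels).
    gene_ids : ndarray of str
        Unique gene identifiers (column labels).
    gene_names : ndarray of str
        Gene symbols used for gene-set matching; need not be unique.
    mito_mask : ndarray of bool
        Flags genes counted as mitochondrial in QC.
    """

    values: sp.csr_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray
    gene_names: np.ndarray
    mito_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.barcodes = _as_str_array(self.barcodes)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.gene_names = _as_str_array(self.gene_names)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        n_cells, n_genes = self.values.shape
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for a matrix with {n_cells} rows"
            )
        for name, arr in (("gene_ids", self.gene_ids), ("gene_names", self.gene_names),
                          ("mito_mask", self.mito_mask)):
            if len(arr) != n_genes:
                raise FormatError(f"{name} has {len(arr)} entries for {n_genes} genes")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("count matrix contains negative entries")
        if not np.allclose(self.values.data, np.round(self.values.data)):
            raise FormatError("count matrix contains non-integer entries")
        if len(np.unique(self.barcodes)) != n_cells:
            raise FormatError("duplicate barcodes")
        if len(np.unique(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene_ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.shape[0] != self.n_cells:
            raise ValueError("cell mask length mismatch")
        return CountMatrix(
            values=self.values[mask],
            barcodes=self.barcodes[mask],
            gene_ids=self.gene_ids,
            gene_names=self.gene_names,
            mito_mask=self.mito_mask,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets; duplicate genes within a set are removed on load."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                if g:
                    seen.setdefault(str(g))
            if not seen:
                raise FormatError(f"gene set {name!r} is empty")
            clean[str(name)] = list(seen)
        self.sets = clean
        self.descriptions = {k: self.descriptions.get(k, "") for k in self.sets}

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def subset(self, names) -> "GeneSetCollection":
        missing = [n for n in names if n not in self.sets]
        if missing:
            raise KeyError(f"gene sets not in collection: {missing}")
        return GeneSetCollection(
            sets={n: list(self.sets[n]) for n in names},
            descriptions={n: self.descriptions[n] for n in names},
        )


def _read_tsv_column(path: Path, n_min_cols: int = 1) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=None, dtype=str)
    except Exception as exc:  # noqa: BLE001 - reported as a format error
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc


def read_mtx_dir(path, mito_prefix: str = "MT-") -> CountMatrix:
    """Read a 10x-style MTX directory into a :class:`CountMatrix`.

    Orientation is auto-detected: if the matrix dimensions match
    (genes, cells) instead of (cells, genes) the matrix is transposed.
    ``mito_mask`` is set from a gene-name prefix (case-sensitive,
    default ``"MT-"``).
    """
    path = Path(path)
    mtx_file = path / "matrix.mtx"
    bc_file = path / "barcodes.tsv"
    ft_file = path / "features.tsv"
    for f in (mtx_file, bc_file, ft_file):
        if not f.exists():
            raise FormatError(f"{f}: file not found")
    try:
        mat = mmread(mtx_file)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{mtx_file}: cannot parse Matrix Market file ({exc})") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        bad = int(np.flatnonzero(~np.isclose(mat.data, np.round(mat.data)))[0])
        raise FormatError(f"{mtx_file}: non-integer value at entry {bad + 1}")

    barcodes = _read_tsv_column(bc_file).iloc[:, 0].to_numpy(dtype=object)
    feats = _read_tsv_column(ft_file)
    if feats.shape[1] < 2:
        raise FormatError(f"{ft_file}: expected at least 2 columns (gene_id, gene_name)")
    gene_ids = feats.iloc[:, 0].to_numpy(dtype=object)
    gene_names = feats.iloc[:, 1].to_numpy(dtype=object)

    n_bc, n_ft = len(barcodes), len(gene_ids)
    if mat.shape == (n_bc, n_ft):
        values = mat.tocsr()
    elif mat.shape == (n_ft, n_bc):
        values = mat.T.tocsr()
    else:
        raise FormatError(
            f"{mtx_file}: matrix is {mat.shape[0]}x{mat.shape[1]} but there are "
            f"{n_bc} barcodes and {n_ft} features"
        )
    mito_mask = np.array([str(g).startswith(mito_prefix) for g in gene_names])
    return CountMatrix(values, barcodes, gene_ids, gene_names, mito_mask)


def write_mtx_dir(counts: CountMatrix, path) -> None:
    """Write a :class:`CountMatrix` as matrix.mtx / barcodes.tsv / features.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts.values)
    mat = mat.astype(np.int64)
    mmwrite(path / "matrix.mtx", mat, comment=f"written by {TOOL_TAG}", field="integer")
    with open(path / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(map(str, counts.barcodes)) + "\n")
    with open(path / "features.tsv", "w") as fh:
        for gid, gname in zip(counts.gene_ids, counts.gene_names):
            fh.write(f"{gid}\t{gname}\tGene Expression\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>gene...``."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a :class:`GeneSetCollection` as GMT (one set per line)."""
    path = Path(path)
    with open(path, "w") as fh:
        for name in collection.names:
            desc = collection.descriptions.get(name, "") or TOOL_TAG
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")
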