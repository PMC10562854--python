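"""Core containers and I/O: sparse count matrices, normalization, downsampling, GMT.

The on-disk exchange format is the CellRanger-style triple — Matrix Market
``matrix.mtx`` with genes as rows (1-based indices), ``genes.tsv`` with gene
metadata and ``cells.tsv`` with cell metadata — all plain text so fixtures and
pipeline artifacts stay diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

VALID_BIOTYPES = ("protein_coding", "lncRNA", "other")
VALID_CONDITIONS = ("healthy", "psoriatic")


class FormatError(ValueError):
    """A file or table violates the format contract (names the offending record)."""


@dataclass
class CellDataset:
    """Sparse non-negative integer counts (cells x genes) with cell and gene metadata.

    Parameters
    ----------
    counts
        CSR matrix of shape ``(n_cells, n_genes)`` holding raw UMI/read counts.
    cell_meta
        DataFrame indexed by unique ``cell_id`` with at least ``dataset``,
        ``donor`` and ``condition`` columns; ``label`` is optional.
    gene_meta
        DataFrame indexed by unique ``gene_id`` with a ``biotype`` column
        (``protein_coding`` / ``lncRNA`` / ``other``).
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_meta), len(self.gene_meta)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match metadata "
                f"({len(self.cell_meta)} cells, {len(self.gene_meta)} genes)"
            )
        for name, idx in (("cell_id", self.cell_meta.index), ("gene_id", self.gene_meta.index)):
            dup = idx[idx.duplicated()]
            if len(dup):
                raise FormatError(f"duplicated {name}: {sorted(set(dup))}")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                bad = np.argwhere(self.counts.toarray() < 0)[0] if self.counts.nnz < 1e6 else None
                where = f" at (cell,gene)={tuple(bad)}" if bad is not None else ""
                raise FormatError(f"negative count entry{where}")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entries present")

    # -- conveniences -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_meta.index

    def subset_cells(self, mask_or_ids) -> "CellDataset":
        """Row-subset keeping metadata aligned; accepts boolean mask or cell ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and np.asarray(mask_or_ids).dtype == bool:
            pos = np.flatnonzero(np.asarray(mask_or_ids))
        else:
            pos = self.cell_meta.index.get_indexer(pd.Index(mask_or_ids))
            if (pos < 0).any():
                raise KeyError("unknown cell ids in subset")
        return CellDataset(self.counts[pos], self.cell_meta.iloc[pos].copy(), self.gene_meta.copy())

    def to_anndata(self):
        """Export to an :class:`anndata.AnnData` (counts in .X) for interop."""
        import anndata as ad

        return ad.AnnData(X=self.counts.copy(), obs=self.cell_meta.copy(), var=self.gene_meta.copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (term_id -> members), as read from a GMT file."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(mtx_path, genes_path, cells_path) -> CellDataset:
    """Read the MTX (genes x cells) + genes.tsv + cells.tsv triple.

    Validates dimensions, uniqueness and non-negative integrality; errors name
    the offending record. Inverse of :func:`write_counts`.
    """
    mat = scipy.io.mmread(str(mtx_path))  # genes x cells on disk
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    if "gene_id" not in genes.columns:
        raise FormatError(f"{genes_path}: missing gene_id column")
    if "cell_id" not in cells.columns:
        raise FormatError(f"{cells_path}: missing cell_id column")
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{mtx_path}: matrix is {mat.shape[0]} genes x {mat.shape[1]} cells but "
            f"genes.tsv has {len(genes)} rows and cells.tsv has {len(cells)} rows"
        )
    coo = sp.coo_matrix(mat)
    neg = np.flatnonzero(coo.data < 0)
    if neg.size:
        i = neg[0]
        raise FormatError(
            f"{mtx_path}: negative entry {coo.data[i]} at gene {genes['gene_id'].iloc[coo.row[i]]}, "
            f"cell {cells['cell_id'].iloc[coo.col[i]]}"
        )
    if not np.allclose(coo.data, np.round(coo.data)):
        i = int(np.flatnonzero(~np.isclose(coo.data, np.round(coo.data)))[0])
        raise FormatError(f"{mtx_path}: non-integer entry {coo.data[i]}")
    counts = sp.csr_matrix(coo.T).astype(np.int64)  # internal: cells x genes
    counts.sort_indices()
    gene_meta = genes.set_index("gene_id")
    cell_meta = cells.set_index("cell_id")
    return CellDataset(counts, cell_meta, gene_meta)


def write_counts(dataset: CellDataset, out_dir) -> Path:
    """Write the dataset as matrix.mtx (genes x rows, canonical order) + TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sp.csr_matrix(dataset.counts.T.astype(np.int64))  # genes x cells
    mat.sort_indices()
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    dataset.gene_meta.reset_index().rename(columns={"index": "gene_id"}).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    dataset.cell_meta.reset_index().rename(columns={"index": "cell_id"}).to_csv(
        out / "cells.tsv", sep="\t", index=False
    )
    return out


def read_dataset_dir(path) -> CellDataset:
    p = Path(path)
    return read_counts(p / "matrix.mtx", p / "genes.tsv", p / "cells.tsv")


def concat_cells(datasets: Sequence[CellDataset]) -> CellDataset:
    """Stack datasets cell-wise; all must share the same gene axis."""
    if not datasets:
        raise ValueError("nothing to concatenate")
    genes = datasets[0].gene_ids
    for ds in datasets[1:]:
        if not genes.equals(ds.gene_ids):
            raise ValueError("datasets must share an identical gene axis to concatenate")
    counts = sp.vstack([ds.counts for ds in datasets], format="csr")
    cell_meta = pd.concat([ds.cell_meta for ds in datasets])
    return CellDataset(counts, cell_meta, datasets[0].gene_meta.copy())


# ---------------------------------------------------------------------------
# normalization


def normalize(dataset: CellDataset, scale: float = 1e4) -> sp.csr_matrix:
    """Library-size normalize then log-transform: ``ln(1 + scale * x / libsize)``.

    Zeros stay zero, so sparsity is preserved. Cells with zero library size are
    rejected (their normalized profile is undefined).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = dataset.counts.astype(np.float64)
    lib = np.asarray(counts.sum(axis=1)).ravel()
    empty = np.flatnonzero(lib == 0)
    if empty.size:
        ids = list(dataset.cell_ids[empty[:10]])
        raise ValueError(f"{empty.size} cell(s) with zero library size, e.g. {ids}")
    out = sp.csr_matrix(counts, copy=True)
    # scale each row by scale/libsize, then log1p on stored entries only
    row_scale = scale / lib
    out.data *= np.repeat(row_scale, np.diff(out.indptr))
    np.log1p(out.data, out=out.data)
    return out


# ---------------------------------------------------------------------------
# downsampling (atlas export rule: at most `cap` cells per cell type, per
# condition, per donor)


def downsample(
    dataset: CellDataset,
    cap: int = 300,
    keys: Sequence[str] = ("label", "condition", "donor"),
    seed: int = 0,
) -> CellDataset:
    """Cap group sizes by uniform subsampling without replacement.

    Within every group defined by ``keys``, at most ``cap`` cells are kept
    (groups at or below the cap are untouched); surviving cells keep their
    original relative order, so the operation is idempotent.
    """
    if cap <= 0:
        raise ValueError("cap must be a positive integer")
    missing = [k for k in keys if k not in dataset.cell_meta.columns]
    if missing:
        raise KeyError(f"cell_meta lacks downsampling key column(s): {missing}")
    rng = np.random.default_rng(seed)
    keep = np.zeros(dataset.n_cells, dtype=bool)
    grouped = dataset.cell_meta.groupby(list(keys), sort=True, observed=True, dropna=False)
    for _, idx in sorted(grouped.indices.items(), key=lambda kv: str(kv[0])):
        idx = np.sort(idx)
        if len(idx) <= cap:
            keep[idx] = True
        else:
            keep[rng.choice(idx, size=cap, replace=False)] = True
    return dataset.subset_cells(keep)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-separated GMT file: ``term<TAB>description<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            term, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {term!r} has no members")
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicated term {term!r}")
            sets[term] = set(members)
            names[term] = desc
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{collection.names.get(term, term)}\t{members}\n")
    return path
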