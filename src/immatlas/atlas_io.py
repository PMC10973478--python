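"""Atlas container and standard-format I/O.

The central object is the :class:`AtlasBundle`: a sparse cells x genes
matrix of raw UMI counts with an aligned per-cell metadata table (organ,
sample, project, optional cell-type annotation and doublet score) and a
gene table carrying the mitochondrial flag.  Every pipeline stage consumes
and produces subsets of this bundle.

On disk the atlas lives in Matrix Market coordinate format plus
tab/comma-delimited barcode and gene tables; a dense delimited reader is
provided for tiny fixtures.  Result tables round-trip losslessly through
TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import io as spio

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"


class AtlasError(ValueError):
    """Raised on violated atlas invariants (dimension mismatch, bad counts)."""


@dataclass
class AtlasBundle:
    """Raw counts + aligned cell metadata + gene table.

    Attributes
    ----------
    counts
        ``(n_cells, n_genes)`` sparse matrix of non-negative integer UMI
        counts (stored CSR).
    cell_meta
        DataFrame indexed by unique barcode; expected columns include
        ``organ``, ``sample_id``, ``project_id`` and optionally
        ``cell_type`` and ``doublet_score``.
    gene_table
        DataFrame indexed by unique gene symbol with a boolean ``is_mito``
        column.
    """

    counts: sp.spmatrix
    cell_meta: pd.DataFrame
    gene_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise AtlasError(
                f"cell count mismatch: counts matrix has {n_cells} cells but "
                f"metadata declares {len(self.cell_meta)} barcodes"
            )
        if len(self.gene_table) != n_genes:
            raise AtlasError(
                f"gene count mismatch: counts matrix has {n_genes} genes but "
                f"gene table declares {len(self.gene_table)}"
            )
        if not self.cell_meta.index.is_unique:
            raise AtlasError("barcodes are not unique")
        if not self.gene_table.index.is_unique:
            raise AtlasError("gene symbols are not unique")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise AtlasError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise AtlasError("counts contain non-integer entries")
        if "is_mito" not in self.gene_table.columns:
            self.gene_table = self.gene_table.assign(
                is_mito=_mito_flags(self.gene_table.index)
            )

    # -- convenience ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_symbols(self) -> pd.Index:
        return self.gene_table.index

    def gene_index(self, symbol: str) -> int:
        try:
            return int(self.gene_table.index.get_loc(symbol))
        except KeyError:
            raise AtlasError(f"gene {symbol!r} not present in the atlas") from None

    def subset(self, cell_mask=None, gene_mask=None) -> "AtlasBundle":
        """Subset cells and/or genes with boolean masks, kept aligned."""
        counts = self.counts
        cell_meta = self.cell_meta
        gene_table = self.gene_table
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask, dtype=bool)
            if cell_mask.shape != (self.n_cells,):
                raise AtlasError(
                    f"cell mask length {cell_mask.size} != {self.n_cells} cells"
                )
            counts = counts[cell_mask]
            cell_meta = cell_meta.loc[cell_mask]
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask, dtype=bool)
            if gene_mask.shape != (self.n_genes,):
                raise AtlasError(
                    f"gene mask length {gene_mask.size} != {self.n_genes} genes"
                )
            counts = counts[:, gene_mask]
            gene_table = gene_table.loc[gene_mask]
        return AtlasBundle(counts, cell_meta.copy(), gene_table.copy())

    def to_anndata(self):
        """Export to an :class:`anndata.AnnData` (lazy import)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(), obs=self.cell_meta.copy(), var=self.gene_table.copy()
        )


def _mito_flags(symbols: Sequence[str], prefix: str = MITO_PREFIX) -> np.ndarray:
    return np.array([str(s).startswith(prefix) for s in symbols], dtype=bool)


def dedupe_symbols(symbols: Sequence[str]) -> list[str]:
    """De-duplicate gene symbols by suffixing ``-1``, ``-2`` ... (logged)."""
    seen: dict[str, int] = {}
    out: list[str] = []
    n_dupes = 0
    for s in map(str, symbols):
        if s in seen:
            seen[s] += 1
            out.append(f"{s}-{seen[s]}")
            n_dupes += 1
        else:
            seen[s] = 0
            out.append(s)
    if n_dupes:
        logger.warning("deduplicated_gene_symbols\tn=%d", n_dupes)
    return out


def _read_table(path) -> pd.DataFrame:
    """Read a tab- or comma-delimited table with header."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep)


def _indexed(table: pd.DataFrame, candidates: tuple[str, ...]) -> pd.DataFrame:
    """Use the first matching column (or the first column) as the index."""
    key = next((c for c in candidates if c in table.columns), table.columns[0])
    return table.set_index(key)


def load_atlas(matrix_path, cells_path, genes_path, mito_prefix: str = MITO_PREFIX) -> AtlasBundle:
    """Load an atlas from Matrix Market counts + barcode/gene tables.

    Orientation (cells x genes vs genes x cells) is auto-detected from the
    dimensions declared by the metadata tables; total UMI is conserved.
    Duplicate gene symbols are de-duplicated by suffixing.  The ``is_mito``
    flag is taken from the gene table when present, otherwise derived from
    the symbol prefix (default ``MT-``).
    """
    cells = _indexed(_read_table(cells_path), ("barcode", "cell", "cell_id"))
    genes = _indexed(_read_table(genes_path), ("gene", "symbol", "gene_symbol"))
    n_cells, n_genes = len(cells), len(genes)

    m = spio.mmread(str(matrix_path))
    if m.shape == (n_cells, n_genes):
        pass
    elif m.shape == (n_genes, n_cells):
        m = m.T
        logger.info("matrix stored genes x cells; transposed to cells x genes")
    else:
        raise AtlasError(
            f"cell count mismatch: matrix shape {m.shape} fits neither "
            f"{n_cells} cells x {n_genes} genes nor its transpose"
        )
    m = sp.csr_matrix(m)
    if m.data.size and (np.any(m.data < 0) or not np.allclose(m.data, np.round(m.data))):
        raise AtlasError("matrix contains negative or non-integer entries")
    m = m.astype(np.int64)

    genes.index = pd.Index(dedupe_symbols(genes.index), name=genes.index.name or "gene")
    if "is_mito" not in genes.columns:
        genes["is_mito"] = _mito_flags(genes.index, mito_prefix)
    else:
        genes["is_mito"] = genes["is_mito"].astype(bool)
    cells.index.name = cells.index.name or "barcode"
    return AtlasBundle(m, cells, genes)


def load_dense_atlas(counts_path, cells_path, mito_prefix: str = MITO_PREFIX) -> AtlasBundle:
    """Read a dense delimited cells x genes count table (tiny fixtures).

    The first column of ``counts_path`` is the barcode; remaining columns
    are gene symbols.  ``cells_path`` supplies the aligned cell metadata.
    """
    dense = _read_table(counts_path)
    dense = dense.set_index(dense.columns[0])
    cells = _indexed(_read_table(cells_path), ("barcode", "cell", "cell_id"))
    if not dense.index.equals(cells.index):
        if len(dense) != len(cells):
            raise AtlasError(
                f"cell count mismatch: dense table has {len(dense)} rows but "
                f"metadata declares {len(cells)}"
            )
        cells = cells.loc[dense.index]
    values = dense.to_numpy()
    if np.any(values < 0) or not np.allclose(values, np.round(values)):
        raise AtlasError("dense table contains negative or non-integer entries")
    genes = pd.DataFrame(index=pd.Index(dedupe_symbols(dense.columns), name="gene"))
    genes["is_mito"] = _mito_flags(genes.index, mito_prefix)
    return AtlasBundle(sp.csr_matrix(values.astype(np.int64)), cells, genes)


def subset_atlas(bundle: AtlasBundle, cell_mask=None, gene_mask=None) -> AtlasBundle:
    """Functional alias for :meth:`AtlasBundle.subset`."""
    return bundle.subset(cell_mask, gene_mask)


def save_atlas(bundle: AtlasBundle, directory) -> dict[str, Path]:
    """Write MTX + TSV files that :func:`load_atlas` reads back."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.mtx",
        "cells": directory / "cells.tsv",
        "genes": directory / "genes.tsv",
    }
    spio.mmwrite(str(paths["matrix"]), bundle.counts.astype(np.int64), field="integer")
    bundle.cell_meta.to_csv(paths["cells"], sep="\t", index_label=bundle.cell_meta.index.name or "barcode")
    bundle.gene_table.to_csv(paths["genes"], sep="\t", index_label=bundle.gene_table.index.name or "gene")
    return paths


def write_results_table(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV; floats keep >= 12 significant digits."""
    if table.shape[1] == 0:
        raise ValueError("result table must have at least one column")
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
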