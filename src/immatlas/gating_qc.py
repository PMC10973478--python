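"""CD45+ gating and quality control.

Immune cells are defined operationally as barcodes with at least one read
of the pan-leukocyte marker gene *PTPRC* (CD45).  Cell-level QC excludes
barcodes with fewer than 1,000 total UMI, fewer than 200 detected genes,
or more than 15% mitochondrial UMI; gene-level QC then drops genes
detected in four or fewer of the surviving cells.  The exclusion rules are
strict inequalities, so a cell sitting exactly on a threshold is retained.

All three gates are per-cell (or per-gene) predicates on the raw counts:
they are idempotent, and the CD45 gate commutes with the cell QC gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .atlas_io import AtlasBundle, AtlasError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """QC gate settings; defaults are the atlas defaults.

    ``max_cells_per_excluded_gene`` = 4 means a gene detected in <= 4 cells
    is excluded (i.e. kept iff detected in >= 5 cells).
    """

    min_umi: int = 1000
    min_genes: int = 200
    max_mito_pct: float = 15.0
    max_cells_per_excluded_gene: int = 4
    cd45_symbol: str = "PTPRC"
    cd45_min_count: int = 1

    def __post_init__(self) -> None:
        for name in ("min_umi", "min_genes", "max_mito_pct",
                     "max_cells_per_excluded_gene", "cd45_min_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"QC threshold {name} must be >= 0")


def cd45_mask(bundle: AtlasBundle, thresholds: QCThresholds = QCThresholds()) -> np.ndarray:
    """Boolean mask of cells with >= ``cd45_min_count`` reads of CD45."""
    try:
        j = bundle.gene_index(thresholds.cd45_symbol)
    except AtlasError:
        raise AtlasError(
            f"CD45 gate gene {thresholds.cd45_symbol!r} is absent from the gene table"
        ) from None
    col = np.asarray(bundle.counts[:, j].todense()).ravel()
    return col >= thresholds.cd45_min_count


def cd45_gate(bundle: AtlasBundle, thresholds: QCThresholds = QCThresholds()) -> AtlasBundle:
    """Retain exactly the cells expressing CD45; log retention per organ."""
    mask = cd45_mask(bundle, thresholds)
    if "organ" in bundle.cell_meta.columns:
        for organ, grp in bundle.cell_meta.groupby("organ", observed=True):
            kept = int(mask[bundle.cell_meta.index.get_indexer(grp.index)].sum())
            logger.info("cd45_gate\torgan=%s\tretained=%d\ttotal=%d", organ, kept, len(grp))
    return bundle.subset(cell_mask=mask)


def cell_qc_mask(bundle: AtlasBundle, thresholds: QCThresholds = QCThresholds()) -> np.ndarray:
    """Conjunction of the UMI, detected-gene and mitochondrial-% rules."""
    counts = bundle.counts
    total = np.asarray(counts.sum(axis=1)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    mito = np.asarray(bundle.gene_table["is_mito"], dtype=bool)
    mito_total = np.asarray(counts[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito_total / np.maximum(total, 1), 0.0)
    n_zero = int((total == 0).sum())
    if n_zero:
        logger.warning("zero_umi_cells_excluded\tn=%d", n_zero)
    return (
        (total >= thresholds.min_umi)
        & (n_genes >= thresholds.min_genes)
        & (mito_pct <= thresholds.max_mito_pct)
    )


def apply_cell_qc(bundle: AtlasBundle, thresholds: QCThresholds = QCThresholds()) -> AtlasBundle:
    return bundle.subset(cell_mask=cell_qc_mask(bundle, thresholds))


def gene_keep_mask(bundle: AtlasBundle, thresholds: QCThresholds = QCThresholds()) -> np.ndarray:
    detected = np.asarray((bundle.counts > 0).sum(axis=0)).ravel()
    return detected > thresholds.max_cells_per_excluded_gene


def apply_gene_filter(bundle: AtlasBundle, thresholds: QCThresholds = QCThresholds()) -> AtlasBundle:
    """Drop genes detected in too few cells (after cell filters)."""
    return bundle.subset(gene_mask=gene_keep_mask(bundle, thresholds))


def run_qc(
    bundle: AtlasBundle, thresholds: QCThresholds = QCThresholds()
) -> tuple[AtlasBundle, dict]:
    """CD45 gate, then cell QC, then the gene filter; returns a report.

    The report carries per-organ retained/excluded counts for the cell
    gates and overall gene counts, suitable for TSV/JSON serialization.
    """
    organ = bundle.cell_meta.get("organ")
    keep_cells = cd45_mask(bundle, thresholds) & cell_qc_mask(bundle, thresholds)
    gated = bundle.subset(cell_mask=keep_cells)
    out = apply_gene_filter(gated, thresholds)

    if organ is not None:
        per_organ = (
            pd.DataFrame({"organ": organ.to_numpy(), "retained": keep_cells})
            .groupby("organ", observed=True)["retained"]
            .agg(retained="sum", total="count")
            .reset_index()
        )
        per_organ["excluded"] = per_organ["total"] - per_organ["retained"]
    else:
        per_organ = pd.DataFrame(
            {"organ": ["all"], "retained": [int(keep_cells.sum())],
             "total": [bundle.n_cells],
             "excluded": [bundle.n_cells - int(keep_cells.sum())]}
        )
    report = {
        "thresholds": asdict(thresholds),
        "cells_in": bundle.n_cells,
        "cells_out": out.n_cells,
        "genes_in": bundle.n_genes,
        "genes_out": out.n_genes,
        "per_organ": per_organ,
    }
    return out, report
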