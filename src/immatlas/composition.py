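"""Cell composition and correlation structure of the atlas.

Covers the cluster x organ over-representation test (upper-tail
hypergeometric on the cell contingency table), per-group pseudobulk
expression profiles, organ-organ Pearson correlation maps, and the
per-cell gene-vs-score correlation check used to rule out doublet-driven
signature genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr

from .atlas_io import AtlasBundle
from .differential_expression import bh_adjust, normalize_counts

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentMap:
    """Tidy hypergeometric enrichment results plus pivot access.

    ``table`` columns: row (subpopulation), col (organ), overlap,
    row_total, col_total, n_total, p_value, neg_log10_p, significant,
    p_bh (BH across all cells of the map, reported for transparency;
    the ``significant`` flag uses the raw p as in the figure convention).
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def pivot(self, value: str = "neg_log10_p") -> pd.DataFrame:
        return self.table.pivot(index="row", columns="col", values=value)


def upper_tail_hypergeom(n_total: int, k_col: int, n_row: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(n_total, k_col, n_row).

    The over-representation probability used for every cell of the
    enrichment map; ``k = 0`` gives 1 (the upper tail includes X = 0).
    """
    p = float(hypergeom.sf(k - 1, n_total, k_col, n_row))
    return min(max(p, 0.0), 1.0)


def hypergeometric_enrichment(
    cell_meta: pd.DataFrame, row_var: str, col_var: str, alpha: float = 0.05
) -> EnrichmentMap:
    """Upper-tail hypergeometric over-representation of row x col groups.

    With N total cells, K cells in column group c, n cells in row group r
    and k their overlap, the p-value is P(X >= k) for
    X ~ Hypergeometric(N, K, n).  Significance is flagged at raw
    ``p < alpha``; a numerically-zero p is reported as the smallest
    positive normal float (logged).
    """
    if len(cell_meta) == 0:
        raise ValueError("empty cell metadata table")
    for col in (row_var, col_var):
        if col not in cell_meta.columns:
            raise ValueError(f"metadata column {col!r} not found")
    rows = cell_meta[row_var].astype(str)
    cols = cell_meta[col_var].astype(str)
    ct = pd.crosstab(rows, cols)
    n_total = int(ct.to_numpy().sum())
    records = []
    for r in ct.index:
        n_r = int(ct.loc[r].sum())
        for c in ct.columns:
            k = int(ct.loc[r, c])
            k_c = int(ct[c].sum())
            p = upper_tail_hypergeom(n_total, k_c, n_r, k)
            if p <= 0.0:
                logger.warning("hypergeom_p_underflow\trow=%s\tcol=%s", r, c)
                p = float(np.finfo(np.float64).tiny)
            p = min(p, 1.0)
            records.append({
                "row": r, "col": c, "overlap": k, "row_total": n_r,
                "col_total": k_c, "n_total": n_total, "p_value": p,
                "neg_log10_p": -np.log10(p), "significant": p < alpha,
            })
    table = pd.DataFrame.from_records(records)
    table["p_bh"] = bh_adjust(table["p_value"].to_numpy())
    return EnrichmentMap(table=table, alpha=alpha)


def pseudobulk_profiles(
    bundle: AtlasBundle,
    group_by: Sequence[str] | str,
    normalized: bool = True,
    scale: float = 1e4,
    log1p: bool = False,
) -> pd.DataFrame:
    """Per-group mean expression profiles (groups x genes).

    With ``normalized`` the per-cell values are depth-normalized to
    ``scale`` counts before averaging; the default averages on the linear
    scale (the behaviour of per-group average-expression utilities in the
    standard single-cell toolchains), ``log1p=True`` averages the
    log-transformed values instead.  Groups with zero cells are omitted.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    for col in group_by:
        if col not in bundle.cell_meta.columns:
            raise ValueError(f"metadata column {col!r} not found")
    if normalized:
        x = normalize_counts(bundle, scale=scale, log1p=log1p)
    else:
        x = bundle.counts.astype(np.float64)
    keys = bundle.cell_meta[list(group_by)].astype(str).agg("/".join, axis=1)
    rows, index = [], []
    for key in sorted(keys.unique()):
        mask = (keys == key).to_numpy()
        rows.append(np.asarray(x[mask].mean(axis=0)).ravel())
        index.append(key)
    return pd.DataFrame(rows, index=pd.Index(index, name="/".join(group_by)),
                        columns=bundle.gene_symbols)


def correlation_matrix(pb: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation across pseudobulk rows.

    Genes with zero variance across groups are dropped first (logged);
    the result is symmetric with a unit diagonal.
    """
    if pb.shape[0] < 2:
        raise ValueError("need >= 2 groups for a correlation matrix")
    values = pb.to_numpy(dtype=float)
    var = values.var(axis=0)
    keep = var > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("correlation_dropped_constant_genes\tn=%d", n_dropped)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 variable genes; correlation undefined")
    r = np.corrcoef(values[:, keep])
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=pb.index, columns=pb.index)


class CorrelationResult(NamedTuple):
    r: float
    n: int
    defined: bool
    message: str = ""


def gene_score_correlation(
    bundle: AtlasBundle,
    gene: str,
    score_column: str,
    within: Optional[str] = None,
    scale: float = 1e4,
) -> CorrelationResult:
    """Pearson r between a gene's normalized expression and a cell score.

    ``within`` restricts to one organ.  Constant expression or score
    yields an undefined-flag result (``r`` is NaN) rather than a number;
    fewer than 3 cells is a hard error.
    """
    if score_column not in bundle.cell_meta.columns:
        raise ValueError(f"score column {score_column!r} not found")
    sub = bundle
    if within is not None:
        sub = bundle.subset(cell_mask=(bundle.cell_meta["organ"].astype(str) == str(within)).to_numpy())
    if sub.n_cells < 3:
        raise ValueError(f"insufficient cells: need >= 3, found {sub.n_cells}")
    j = sub.gene_index(gene)
    expr = np.asarray(normalize_counts(sub, scale=scale)[:, j].todense()).ravel()
    score = sub.cell_meta[score_column].to_numpy(dtype=float)
    if np.ptp(expr) == 0 or np.ptp(score) == 0:
        msg = "constant expression" if np.ptp(expr) == 0 else "constant score"
        logger.warning("gene_score_correlation_undefined\tgene=%s\treason=%s", gene, msg)
        return CorrelationResult(float("nan"), sub.n_cells, False, msg)
    r, _ = pearsonr(expr, score)
    return CorrelationResult(float(r), sub.n_cells, True)
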