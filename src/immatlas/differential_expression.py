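"""Normalization and one-vs-rest Wilcoxon differential expression.

Counts are depth-normalized per cell and log-transformed,
``ln(1 + scale * count / total UMI)`` with ``scale`` = 10,000.  For each
group (an organ, or a cluster) the group's cells are tested against the
pooled cells of all other groups, optionally within a stratifying variable
(e.g. organ-vs-rest within each immune cell type).  A comparison runs only
when both sides have at least ``min_cells`` cells (default 40); a gene is
tested only when it is expressed in strictly more than ``min_pct`` of the
group's cells (default 50%) and its |log2 fold change| clears
``min_abs_log2fc`` (default 0.25).  P-values come from the two-sided
Wilcoxon rank-sum test — exact enumeration for small samples, tie- and
continuity-corrected normal approximation otherwise — and are
Benjamini-Hochberg adjusted within each comparison.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .atlas_io import AtlasBundle

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # exact enumeration when n1 + n2 <= this


def normalize_counts(bundle: AtlasBundle, scale: float = 1e4, log1p: bool = True) -> sp.csr_matrix:
    """Depth-normalize counts; zero stays zero.

    With ``log1p`` (default) returns ``ln(1 + scale * c / total)``;
    otherwise the linear depth-normalized values ``scale * c / total``.
    Cells with zero total UMI are a hard error (QC removes them).
    """
    counts = sp.csr_matrix(bundle.counts, dtype=np.float64, copy=True)
    total = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(total == 0):
        raise ValueError(
            f"{int((total == 0).sum())} cells have zero total UMI; apply QC first"
        )
    scaling = sp.diags(scale / total)
    x = scaling @ counts
    if log1p:
        x.data = np.log1p(x.data)
    return sp.csr_matrix(x)


def wilcoxon_test(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(U, p)``.

    ``U`` is the Mann-Whitney statistic for ``x`` built from average ranks.
    ``method``: ``"exact"`` enumerates all labelings (used automatically
    when ``n1 + n2 <= 12``; handles ties), ``"asymptotic"`` uses the tie-
    and continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:  # full ties: no evidence either way
        return n1 * n2 / 2.0, 1.0
    if method == "exact" or (method == "auto" and n1 + n2 <= EXACT_MAX_N):
        return _wilcoxon_exact(combined, n1)
    u, p = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u), float(min(max(p, np.finfo(float).tiny), 1.0))


def _wilcoxon_exact(combined: np.ndarray, n1: int) -> tuple[float, float]:
    """Exact two-sided p by enumerating all C(n, n1) labelings."""
    n = combined.size
    ranks = rankdata(combined)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * (n - n1) / 2.0
    dev_obs = abs(u_obs - mu) - 1e-12
    hits = total = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= dev_obs:
            hits += 1
    return float(u_obs), hits / total


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class DEResults(NamedTuple):
    """One-vs-rest DE output.

    ``table`` has one row per tested (stratum, group, gene);
    ``comparisons`` lists every comparison that ran (sizes and number of
    genes tested); ``skipped`` lists comparisons vetoed by the
    ``min_cells`` gate.
    """

    table: pd.DataFrame
    comparisons: pd.DataFrame
    skipped: pd.DataFrame


_TABLE_COLS = ["stratum", "group", "gene", "log2fc", "pct_in", "pct_out",
               "u_stat", "p_value", "p_adjusted", "direction"]


def one_vs_rest_de(
    bundle: AtlasBundle,
    group_var: str,
    within: Optional[str] = None,
    min_cells: int = 40,
    min_pct: float = 0.5,
    min_abs_log2fc: float = 0.25,
    scale: float = 1e4,
) -> DEResults:
    """One-vs-rest Wilcoxon DE for every level of ``group_var``.

    With ``within`` set, the analysis is repeated independently inside
    each stratum (e.g. each immune cell type), and "rest" pools the other
    groups' cells of the same stratum only.  log2 fold changes are
    computed between mean depth-normalized expression of the two sides
    (with a pseudocount of 1); percent-expressing gates use raw counts.
    BH adjustment is per comparison, over its tested genes.
    """
    for col in filter(None, (group_var, within)):
        if col not in bundle.cell_meta.columns:
            raise ValueError(f"metadata column {col!r} not found")

    linear = normalize_counts(bundle, scale=scale, log1p=False)  # ranks are shared with log1p
    detected = sp.csr_matrix(bundle.counts > 0, dtype=np.float64)

    meta = bundle.cell_meta
    strata = [("all", np.ones(bundle.n_cells, dtype=bool))] if within is None else [
        (str(level), (meta[within] == level).to_numpy())
        for level in sorted(map(str, meta[within].astype(str).unique()))
    ]

    rows: list[dict] = []
    ran: list[dict] = []
    skipped: list[dict] = []
    genes = bundle.gene_symbols.to_numpy()

    for stratum_name, smask in strata:
        groups = meta.loc[smask, group_var].astype(str)
        for level in sorted(groups.unique()):
            in_mask = smask & (meta[group_var].astype(str) == level).to_numpy()
            out_mask = smask & ~in_mask
            n_in, n_out = int(in_mask.sum()), int(out_mask.sum())
            if n_in < min_cells or n_out < min_cells:
                skipped.append({"stratum": stratum_name, "group": level,
                                "n_in": n_in, "n_out": n_out})
                logger.warning("skipped_comparison\tstratum=%s\tgroup=%s\tn_in=%d\tn_out=%d",
                               stratum_name, level, n_in, n_out)
                continue

            # sum-then-divide keeps boundary fractions (e.g. exactly 50%) exact
            pct_in = np.asarray(detected[in_mask].sum(axis=0)).ravel() / n_in
            pct_out = np.asarray(detected[out_mask].sum(axis=0)).ravel() / n_out
            mean_in = np.asarray(linear[in_mask].mean(axis=0)).ravel()
            mean_out = np.asarray(linear[out_mask].mean(axis=0)).ravel()
            log2fc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)
            tested = (pct_in > min_pct) & (np.abs(log2fc) >= min_abs_log2fc)
            t_idx = np.flatnonzero(tested)
            ran.append({"stratum": stratum_name, "group": level,
                        "n_in": n_in, "n_out": n_out, "n_tested": len(t_idx)})
            if len(t_idx) == 0:
                continue

            x_in = np.asarray(linear[in_mask][:, t_idx].todense())
            x_out = np.asarray(linear[out_mask][:, t_idx].todense())
            pvals, ustats = np.empty(len(t_idx)), np.empty(len(t_idx))
            for k in range(len(t_idx)):
                ustats[k], pvals[k] = wilcoxon_test(x_in[:, k], x_out[:, k])
            padj = bh_adjust(pvals)
            for k, j in enumerate(t_idx):
                rows.append({
                    "stratum": stratum_name, "group": level, "gene": genes[j],
                    "log2fc": log2fc[j], "pct_in": pct_in[j], "pct_out": pct_out[j],
                    "u_stat": ustats[k], "p_value": pvals[k], "p_adjusted": padj[k],
                    "direction": "up" if log2fc[j] > 0 else "down",
                })

    table = pd.DataFrame(rows, columns=_TABLE_COLS)
    comparisons = pd.DataFrame(ran, columns=["stratum", "group", "n_in", "n_out", "n_tested"])
    skipped_df = pd.DataFrame(skipped, columns=["stratum", "group", "n_in", "n_out"])
    return DEResults(table, comparisons, skipped_df)
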