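"""Rank-based gene-module scoring.

Two scorers are provided: the per-cell UCell statistic for single-cell
data and the single-sample GSEA (ssGSEA) score for bulk validation
profiles, plus group comparisons of the resulting scores.

The UCell score for a cell is built from the ranks of the signature genes
among all genes, ranked by decreasing expression with average ranks on
ties (all-zero genes therefore share the tied bottom ranks).  Ranks above
``max_rank`` are capped at ``max_rank + 1``; with n signature genes and
rank sum R, U' = R - n(n+1)/2 and the score is ``1 - U'/(n * max_rank)``,
clamped to [0, 1].  Being rank-based, the score is invariant to any
strictly monotone transform of a cell's expression values, hence robust
to sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .atlas_io import AtlasBundle
from .differential_expression import bh_adjust, wilcoxon_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty list of unique gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file (name, description, genes...; tab-separated)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, genes = fields[0], [g for g in fields[2:] if g.strip()]
            # preserve order, drop duplicates
            genes = list(dict.fromkeys(genes))
            sets.append(GeneSet(name=name, genes=tuple(genes)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")


def ucell_score(
    bundle: AtlasBundle, gene_set: GeneSet, max_rank: int = 1500, chunk: int = 2000
) -> pd.Series:
    """Per-cell UCell score of ``gene_set``; returns a barcode-keyed Series.

    Genes of the set missing from the atlas are dropped (logged); an
    empty intersection is a hard error.
    """
    present = [g for g in gene_set.genes if g in bundle.gene_table.index]
    missing = len(gene_set) - len(present)
    if missing:
        logger.warning("ucell_missing_genes\tset=%s\tn=%d", gene_set.name, missing)
    if not present:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the atlas")
    idx = np.array([bundle.gene_index(g) for g in present])
    n = len(idx)
    scores = np.empty(bundle.n_cells)
    for start in range(0, bundle.n_cells, chunk):
        block = np.asarray(bundle.counts[start:start + chunk].todense(), dtype=float)
        ranks = rankdata(-block, axis=1)  # rank 1 = highest expression; ties averaged
        r = np.minimum(ranks[:, idx], max_rank + 1)
        u = r.sum(axis=1) - n * (n + 1) / 2.0
        scores[start:start + chunk] = 1.0 - u / (n * max_rank)
    return pd.Series(np.clip(scores, 0.0, 1.0), index=bundle.barcodes,
                     name=f"ucell_{gene_set.name}")


def ssgsea_score(profile: pd.Series, gene_set: GeneSet, alpha: float = 0.25) -> float:
    """Single-sample GSEA score of one expression profile.

    Genes are ordered by decreasing expression; the score is the sum over
    ranks of the difference between the in-set ECDF (steps weighted by
    expression rank^alpha) and the uniform out-of-set ECDF.  A constant
    profile has no ordering: the result is NaN (logged), not a number.
    """
    values = profile.to_numpy(dtype=float)
    in_set = np.asarray(profile.index.isin(gene_set.genes))
    if not in_set.any():
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the profile")
    if np.ptp(values) == 0:
        logger.warning("ssgsea_undefined\tset=%s\treason=constant_profile", gene_set.name)
        return float("nan")
    order = np.argsort(-values, kind="stable")
    hit = in_set[order]
    n = len(values)
    n_hit = int(hit.sum())
    if n_hit == n:
        raise ValueError("gene set covers the whole profile; out-of-set ECDF undefined")
    # weight of a hit at sorted position i: (rank from bottom)^alpha
    rank_from_bottom = rankdata(values)[order]  # ties averaged
    w = np.where(hit, rank_from_bottom ** alpha, 0.0)
    cdf_in = np.cumsum(w) / w.sum()
    cdf_out = np.cumsum(~hit) / (n - n_hit)
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_scores(
    profiles: pd.DataFrame,
    sets: Sequence[GeneSet],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA over samples x genes profiles; optional range normalization.

    ``normalize=True`` divides all scores by the global score range
    across samples and sets (the multi-sample convention); it is off by
    default for single-profile use.
    """
    out = pd.DataFrame(
        {s.name: [ssgsea_score(profiles.loc[i], s, alpha) for i in profiles.index]
         for s in sets},
        index=profiles.index,
    )
    if normalize:
        span = np.nanmax(out.to_numpy()) - np.nanmin(out.to_numpy())
        if span > 0:
            out = out / span
    return out


class GroupComparison(NamedTuple):
    group_stats: pd.DataFrame  # group, n, median, mean
    pairwise: pd.DataFrame     # group_a, group_b, u_stat, p_value, p_adjusted, winner


def compare_group_scores(
    scores: pd.Series, cell_meta: pd.DataFrame, group_var: str, min_cells: int = 3
) -> GroupComparison:
    """Compare score distributions across groups.

    Groups with fewer than ``min_cells`` cells are dropped with a warning;
    at least two groups must remain.  All group pairs are tested with the
    two-sided Wilcoxon rank-sum test and BH-adjusted; ``winner`` is the
    group with the higher median.
    """
    if group_var not in cell_meta.columns:
        raise ValueError(f"metadata column {group_var!r} not found")
    groups = cell_meta.loc[scores.index, group_var].astype(str)
    kept: dict[str, np.ndarray] = {}
    for level in sorted(groups.unique()):
        vals = scores[groups == level].to_numpy(dtype=float)
        if len(vals) < min_cells:
            logger.warning("score_group_dropped\tgroup=%s\tn=%d", level, len(vals))
            continue
        kept[level] = vals
    if len(kept) < 2:
        raise ValueError(f"need >= 2 groups with >= {min_cells} cells")
    stats = pd.DataFrame(
        [{"group": g, "n": len(v), "median": float(np.median(v)), "mean": float(np.mean(v))}
         for g, v in kept.items()]
    )
    rows = []
    for a, b in combinations(kept, 2):
        u, p = wilcoxon_test(kept[a], kept[b])
        winner = a if np.median(kept[a]) > np.median(kept[b]) else b
        if np.median(kept[a]) == np.median(kept[b]):
            winner = "tie"
        rows.append({"group_a": a, "group_b": b, "u_stat": u, "p_value": p, "winner": winner})
    pairwise = pd.DataFrame(rows)
    pairwise.insert(4, "p_adjusted", bh_adjust(pairwise["p_value"].to_numpy()))
    return GroupComparison(stats, pairwise)
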