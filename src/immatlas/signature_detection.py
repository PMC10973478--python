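"""Organ-specific gene-signature detection.

Within each immune cell type, every organ is tested against the pooled
cells of all other organs (one-vs-rest Wilcoxon DE with the 40-cell and
>50%-expressing gates).  Candidate genes — significantly up-regulated in
exactly one organ's comparison — are then screened for uniqueness on the
per-organ pseudobulk table: a gene survives only if its pseudobulk value
in the target organ is at least ``margin`` times the maximum across all
other organs (default margin 2).  The authors' hierarchical-cluster
screening step on the pseudobulk table is operationalized by this
deterministic margin rule; an average-linkage dendrogram on 1 - Pearson
distance over the surviving genes is still emitted (as Newick) for
inspection.  A sharing analysis then asks, per (gene, organ), what
fraction of the analyzed cell types carry the gene in their signature;
strictly more than 50% flags a pan-cell-type organ gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .atlas_io import AtlasBundle
from .composition import pseudobulk_profiles
from .differential_expression import one_vs_rest_de

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    """Uniqueness-screen settings.

    ``fdr``: BH-adjusted significance cutoff on the DE candidates.
    ``margin``: required ratio of target-organ pseudobulk to the maximum
    pseudobulk across other organs (must exceed 1).
    """

    fdr: float = 0.05
    margin: float = 2.0
    linkage_method: str = "average"
    distance: str = "pearson"

    def __post_init__(self) -> None:
        if self.margin <= 1:
            raise ValueError("uniqueness margin must be > 1")


@dataclass(frozen=True)
class DEParams:
    min_cells: int = 40
    min_pct: float = 0.5
    min_abs_log2fc: float = 0.25
    scale: float = 1e4


@dataclass
class OrganSignature:
    organ: str
    cell_type: str
    genes: pd.DataFrame  # per-gene: log2fc, pct_in, p_adjusted, pb_target, pb_other_max, uniqueness_ratio
    screen_params: dict = field(default_factory=dict)

    @property
    def gene_list(self) -> list[str]:
        return list(self.genes["gene"])


@dataclass
class SignatureResult:
    signatures: list[OrganSignature]
    analyzed: pd.DataFrame      # (cell_type, organ) comparisons that ran
    skipped: pd.DataFrame       # comparisons vetoed by the min_cells gate
    dendrograms: dict[str, str]  # cell_type -> Newick
    direction: str = "up"

    def table(self) -> pd.DataFrame:
        frames = []
        for sig in self.signatures:
            df = sig.genes.copy()
            df.insert(0, "cell_type", sig.cell_type)
            df.insert(0, "organ", sig.organ)
            frames.append(df)
        cols = ["organ", "cell_type", "gene", "log2fc", "pct_in",
                "p_adjusted", "pb_target", "pb_other_max", "uniqueness_ratio"]
        if not frames:
            return pd.DataFrame(columns=cols)
        return pd.concat(frames, ignore_index=True)[cols]


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = to_tree(z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def _dendrogram_newick(pb: pd.DataFrame, genes: list[str], method: str) -> str:
    """Average-linkage tree of signature genes on 1 - Pearson distance."""
    genes = [g for g in genes if g in pb.columns]
    if len(genes) == 0:
        return ";"
    if len(genes) == 1:
        return f"({genes[0]}:0);"
    values = pb[genes].to_numpy(dtype=float).T  # genes x organs
    sd = values.std(axis=1)
    corr = np.corrcoef(values)
    corr[~np.isfinite(corr)] = 0.0  # constant gene rows: treat as uncorrelated
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=method)
    return _linkage_to_newick(z, genes)


def uniqueness_screen(
    candidates: pd.DataFrame,
    pb: pd.DataFrame,
    margin: float = 2.0,
    linkage_method: str = "average",
    distance: str = "pearson",
    direction: str = "up",
) -> tuple[pd.DataFrame, str]:
    """Screen DE-unique candidates on the pseudobulk table.

    ``candidates`` rows carry at least (group, gene, ...) where ``group``
    is the organ; they must already be unique-up (or unique-down) genes.
    ``pb`` is the organs x genes pseudobulk table for the cell type under
    test.  Returns the retained rows (with pseudobulk annotations) and a
    Newick dendrogram over the retained genes.
    """
    if margin <= 1:
        raise ValueError("uniqueness margin must be > 1")
    if distance != "pearson":
        raise ValueError("only the pearson dendrogram distance is supported")
    kept_rows = []
    for _, row in candidates.iterrows():
        organ, gene = str(row["group"]), row["gene"]
        if gene not in pb.columns or organ not in pb.index:
            continue
        target = float(pb.loc[organ, gene])
        others = pb.loc[pb.index != organ, gene].to_numpy(dtype=float)
        if direction == "up":
            other_ref = float(others.max()) if others.size else 0.0
            ratio = target / other_ref if other_ref > 0 else np.inf
            keep = target >= margin * other_ref
        else:  # uniquely reduced: target at most other minimum / margin
            other_ref = float(others.min()) if others.size else 0.0
            ratio = other_ref / target if target > 0 else np.inf
            keep = margin * target <= other_ref
        if keep:
            rec = dict(row)
            rec.update(pb_target=target, pb_other_max=other_ref, uniqueness_ratio=ratio)
            kept_rows.append(rec)
    kept = pd.DataFrame(kept_rows)
    newick = _dendrogram_newick(pb, list(kept["gene"]) if len(kept) else [], linkage_method)
    return kept, newick


def detect_organ_signatures(
    bundle: AtlasBundle,
    cell_type_var: str = "cell_type",
    organ_var: str = "organ",
    de_params: Optional[DEParams] = None,
    screen_params: Optional[ScreenParams] = None,
    direction: str = "up",
) -> SignatureResult:
    """Run the full organ-signature procedure on a QC'd bundle.

    Per cell type: one-vs-rest DE across organs, keep genes significant in
    the requested direction in exactly one organ's comparison (organs
    skipped for the 40-cell gate cannot veto uniqueness), then apply the
    pseudobulk margin screen.  Cell types represented in fewer than two
    organs are skipped with a warning.
    """
    de_params = de_params or DEParams()
    screen_params = screen_params or ScreenParams()
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    for col in (cell_type_var, organ_var):
        if col not in bundle.cell_meta.columns:
            raise ValueError(f"metadata column {col!r} not found")

    signatures: list[OrganSignature] = []
    analyzed_rows: list[dict] = []
    skipped_frames: list[pd.DataFrame] = []
    dendrograms: dict[str, str] = {}

    cell_types = sorted(bundle.cell_meta[cell_type_var].astype(str).unique())
    for ct in cell_types:
        mask = (bundle.cell_meta[cell_type_var].astype(str) == ct).to_numpy()
        sub = bundle.subset(cell_mask=mask)
        organs = sub.cell_meta[organ_var].astype(str).unique()
        if len(organs) < 2:
            logger.warning("signature_skipped_cell_type\tcell_type=%s\treason=single_organ", ct)
            continue
        de = one_vs_rest_de(
            sub, organ_var,
            min_cells=de_params.min_cells, min_pct=de_params.min_pct,
            min_abs_log2fc=de_params.min_abs_log2fc, scale=de_params.scale,
        )
        for _, comp in de.comparisons.iterrows():
            analyzed_rows.append({"cell_type": ct, "organ": comp["group"],
                                  "n_in": comp["n_in"], "n_out": comp["n_out"]})
        if len(de.skipped):
            skipped_frames.append(de.skipped.assign(cell_type=ct))
        sig_hits = de.table[
            (de.table["direction"] == direction)
            & (de.table["p_adjusted"] < screen_params.fdr)
        ]
        if len(sig_hits) == 0:
            dendrograms[ct] = ";"
            continue
        # rule (a): significant in exactly one organ's comparison
        per_gene = sig_hits.groupby("gene")["group"].nunique()
        unique_genes = set(per_gene[per_gene == 1].index)
        candidates = sig_hits[sig_hits["gene"].isin(unique_genes)]
        pb = pseudobulk_profiles(sub, organ_var, normalized=True, scale=de_params.scale)
        kept, newick = uniqueness_screen(
            candidates[["group", "gene", "log2fc", "pct_in", "p_adjusted"]],
            pb, margin=screen_params.margin,
            linkage_method=screen_params.linkage_method,
            distance=screen_params.distance, direction=direction,
        )
        dendrograms[ct] = newick
        if len(kept) == 0:
            continue
        for organ, grp in kept.groupby("group"):
            genes_df = grp.drop(columns=["group"]).reset_index(drop=True)
            signatures.append(OrganSignature(
                organ=str(organ), cell_type=ct, genes=genes_df,
                screen_params=asdict(screen_params),
            ))

    analyzed = pd.DataFrame(analyzed_rows, columns=["cell_type", "organ", "n_in", "n_out"])
    skipped = (pd.concat(skipped_frames, ignore_index=True)
               if skipped_frames else pd.DataFrame(columns=["stratum", "group", "n_in", "n_out", "cell_type"]))
    return SignatureResult(signatures, analyzed, skipped, dendrograms, direction)


def signature_sharing(result: SignatureResult) -> pd.DataFrame:
    """Cross-cell-type sharing of signature genes.

    Per (gene, organ): fraction of cell types analyzed for that organ
    whose signature contains the gene; strictly greater than 0.5 sets
    ``shared_flag``.
    """
    if len(result.signatures) == 0:
        return pd.DataFrame(columns=["gene", "organ", "n_cell_types_detected",
                                     "n_cell_types_analyzed", "sharing_fraction", "shared_flag"])
    analyzed_cts = result.analyzed.groupby("organ")["cell_type"].nunique()
    records: dict[tuple[str, str], set[str]] = {}
    for sig in result.signatures:
        for gene in sig.gene_list:
            records.setdefault((gene, sig.organ), set()).add(sig.cell_type)
    rows = []
    for (gene, organ), cts in sorted(records.items()):
        n_analyzed = int(analyzed_cts.get(organ, 0))
        frac = len(cts) / n_analyzed if n_analyzed else 0.0
        rows.append({
            "gene": gene, "organ": organ,
            "n_cell_types_detected": len(cts),
            "n_cell_types_analyzed": n_analyzed,
            "sharing_fraction": frac,
            "shared_flag": frac > 0.5,
        })
    return pd.DataFrame(rows)
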