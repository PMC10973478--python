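# immatlas

Analysis pipeline for multi-organ immune-cell atlases built from
single-cell RNA-seq count matrices. It targets the common workflow of
cross-organ immune meta-atlases: select the immune (CD45+/*PTPRC*+)
compartment, apply per-cell and per-gene quality control, quantify which
immune subpopulations are over-represented in which organs, find genes
uniquely over-expressed in one organ within each immune cell type, score
gene modules (e.g. NFkB target genes) per cell, and run gene-set
enrichment on the resulting rankings. A synthetic-atlas generator with
planted, recorded truths makes every stage testable by parameter
recovery — no downloads required.

Intended users: computational biologists who want the organ-signature
procedure and its supporting statistics as reusable, tested library
functions rather than a one-off analysis script.

## Methods at a glance

- **Gating/QC** — a cell is immune iff it has ≥ 1 read of *PTPRC*; cells
  with < 1,000 UMI, < 200 detected genes or > 15% mitochondrial UMI are
  excluded (strict inequalities: boundary cells are kept), then genes
  detected in ≤ 4 cells are dropped.
- **Composition** — for subpopulation r and organ c with overlap k in a
  table of N cells (K in the organ, n in the subpopulation), the
  enrichment p-value is the upper tail P(X ≥ k), X ~ Hypergeom(N, K, n).
- **Differential expression** — one-vs-rest two-sided Wilcoxon rank-sum
  on ln(1 + 10⁴·c/total) normalized counts, within each immune cell
  type; a comparison needs ≥ 40 cells on both sides, a gene is tested
  only if expressed in > 50% of the group and |log₂FC| ≥ 0.25;
  Benjamini–Hochberg adjustment per comparison. Exact enumeration is
  used when n₁+n₂ ≤ 12, a tie- and continuity-corrected normal
  approximation otherwise.
- **Organ signatures** — genes significantly up in exactly one organ's
  comparison, then screened on the per-organ pseudobulk table: kept iff
  pseudobulk(target organ) ≥ 2 × max pseudobulk(other organs). A gene in
  the signatures of > 50% of the analyzed cell types for an organ is a
  pan-cell-type organ gene.
- **Module scoring** — per-cell UCell statistic
  `1 − U′/(n·maxRank)` on capped expression ranks (rank-based, hence
  depth-robust), and ssGSEA for bulk validation profiles.
- **GSEA** — preranked running-sum enrichment score, gene-label
  permutation null, NES and BH-FDR, plus a cross-organ summary of
  uniquely vs broadly enriched pathways.

## Worked example

```python
from immatlas import (demo_design, simulate_atlas, run_qc,
                      detect_organ_signatures, signature_sharing,
                      ucell_score, compare_group_scores, GeneSet)

design = demo_design(seed=1)          # 4 organs x 3 cell types, planted truths
bundle, truth = simulate_atlas(design)
gated, report = run_qc(bundle)
result = detect_organ_signatures(gated)
for sig in result.signatures:
    print(f"{sig.organ:>8} / {sig.cell_type:<8}: {', '.join(sig.gene_list)}")
```

prints

```
  kidney / B       : GPX3s
  thymus / B       : DNTTs, ACVR2Bs, NFKBT01, ..., NFKBT20
  kidney / T_NK    : GPX3s
  thymus / T_NK    : DNTTs, ACVR2Bs
  kidney / myeloid : GPX3s
  thymus / myeloid : DNTTs, ACVR2Bs
```

The demo design plants a kidney-specific gene (`GPX3s`) and two
thymus-specific genes (`DNTTs`, `ACVR2Bs`) across all cell types at
fold 6 and 4, plus a 20-gene module activated at fold 4 only in thymic
B cells — every planted gene is recovered in the right organ, the
module genes surface only in the thymus/B signature (where they truly
are uniquely elevated), and nothing else passes the screen. The sharing
analysis flags exactly the three pan-cell-type plants
(`sharing_fraction = 1.0`); UCell scoring of the module separates the
active stratum cleanly (median 0.89 in thymus/B vs ≤ 0.71 elsewhere,
1,538 QC-passing cells of 1,800 simulated).

The same pipeline runs from the shell:

```sh
immatlas all --seed 1 --outdir out            # demo simulation end to end
immatlas qc --config my_atlas.yaml            # real MTX/TSV inputs per stage
```

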