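"""Config-driven orchestration of the analysis stages.

Stages: simulate | qc | composition | de | signatures | score | gsea |
report.  Each stage writes its tables into ``<outdir>/<stage>/`` together
with a JSON provenance block (package version, SHA-256 of the canonical
config, seed) so a deterministic stage re-runs bit-identically from the
same config and inputs.  A stage whose dependency outputs are missing is
a hard error naming the missing stage; partially written outputs are
removed on failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .atlas_io import AtlasBundle, load_atlas, save_atlas, write_results_table
from .composition import correlation_matrix, hypergeometric_enrichment, pseudobulk_profiles
from .differential_expression import one_vs_rest_de
from .gating_qc import QCThresholds, run_qc
from .gsea import pathway_uniqueness, preranked_gsea
from .module_scoring import GeneSet, compare_group_scores, read_gmt, ucell_score
from .signature_detection import DEParams, ScreenParams, detect_organ_signatures, signature_sharing
from .synthetic_data import (GroundTruth, MarkerGene, ModuleActivation,
                             PlantedGene, SimulationDesign, demo_design, simulate_atlas)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "composition", "de", "signatures", "score", "gsea", "report")

# stage -> stages whose outputs it needs
_DEPS = {
    "simulate": (),
    "qc": (),            # needs an atlas: simulate outputs or config input paths
    "composition": ("qc",),
    "de": ("qc",),
    "signatures": ("qc",),  # runs its own stratified DE
    "score": ("qc",),
    "gsea": ("de",),
    "report": (),
}


class PipelineError(RuntimeError):
    pass


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _provenance(outdir: Path, stage: str, config: dict, seed: int) -> None:
    block = {"package": "immatlas", "version": __version__, "stage": stage,
             "seed": seed, "config_sha256": config_hash(config)}
    (outdir / stage / f"{stage}.provenance.json").write_text(json.dumps(block, indent=1))


def design_from_config(cfg: dict, seed: int) -> SimulationDesign:
    """Build a SimulationDesign from the ``simulate:`` config section."""
    cfg = dict(cfg or {})
    if cfg.pop("demo", False) or not cfg:
        return demo_design(seed, **{k: cfg[k] for k in ("cells_per_stratum", "n_genes") if k in cfg})
    kwargs = dict(cfg)
    kwargs["seed"] = kwargs.get("seed", seed)
    for key, cls in (("organ_specific", PlantedGene), ("cell_type_markers", MarkerGene),
                     ("module_active_strata", ModuleActivation)):
        if key in kwargs:
            kwargs[key] = tuple(cls(**d) for d in kwargs[key])
    for key in ("organs", "cell_types", "module_genes"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimulationDesign(**kwargs)


def _load_qc_bundle(outdir: Path) -> AtlasBundle:
    qc_dir = outdir / "qc" / "atlas"
    if not qc_dir.exists():
        raise PipelineError("missing dependency stage: qc (run it first)")
    return load_atlas(qc_dir / "matrix.mtx", qc_dir / "cells.tsv", qc_dir / "genes.tsv")


def _truth_path(outdir: Path) -> Optional[Path]:
    p = outdir / "simulate" / "ground_truth.json"
    return p if p.exists() else None


def _ranking_from_de(de_table: pd.DataFrame, stratum: str, group: str) -> pd.Series:
    sub = de_table[(de_table["stratum"].astype(str) == stratum)
                   & (de_table["group"].astype(str) == group)]
    score = np.sign(sub["log2fc"].to_numpy()) * -np.log10(np.maximum(sub["p_value"].to_numpy(), 1e-300))
    return pd.Series(score, index=pd.Index(sub["gene"], name="gene"))


def run_pipeline(config: dict, stages: Iterable[str], outdir=None, seed: Optional[int] = None) -> dict:
    """Execute the requested stages; returns a summary dict.

    ``config`` is a plain mapping (typically parsed from YAML); ``outdir``
    and ``seed`` override the config's values.
    """
    config = dict(config or {})
    outdir = Path(outdir or config.get("outdir", "immatlas_out"))
    seed = int(seed if seed is not None else config.get("seed", 0))
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    # fail fast on missing configured inputs
    input_cfg = config.get("input") or {}
    if "qc" in stages and "simulate" not in stages and not (outdir / "simulate" / "atlas").exists():
        if not input_cfg:
            raise PipelineError("qc stage needs simulated outputs or an input: section")
        for key in ("matrix", "cells", "genes"):
            path = input_cfg.get(key)
            if not path or not Path(path).exists():
                raise PipelineError(f"configured input path missing: {key}={path!r}")

    summary: dict = {"outdir": str(outdir), "seed": seed, "stages": stages}
    for stage in stages:
        for dep in _DEPS[stage]:
            if dep not in stages and not (outdir / dep).exists():
                raise PipelineError(f"missing dependency stage: {dep}")
        stage_dir = outdir / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        try:
            _STAGE_FUNCS[stage](config, outdir, seed, summary)
            _provenance(outdir, stage, config, seed)
        except Exception:
            shutil.rmtree(stage_dir, ignore_errors=True)
            raise
        logger.info("stage_complete\tstage=%s", stage)
    return summary


# -- stage implementations ----------------------------------------------

def _stage_simulate(config: dict, outdir: Path, seed: int, summary: dict) -> None:
    design = design_from_config(config.get("simulate"), seed)
    bundle, truth = simulate_atlas(design)
    save_atlas(bundle, outdir / "simulate" / "atlas")
    truth.to_json(outdir / "simulate" / "ground_truth.json")
    summary["simulate"] = {"n_cells": bundle.n_cells, "n_genes": bundle.n_genes}


def _stage_qc(config: dict, outdir: Path, seed: int, summary: dict) -> None:
    sim_dir = outdir / "simulate" / "atlas"
    if sim_dir.exists():
        bundle = load_atlas(sim_dir / "matrix.mtx", sim_dir / "cells.tsv", sim_dir / "genes.tsv")
    else:
        paths = config.get("input") or {}
        bundle = load_atlas(paths["matrix"], paths["cells"], paths["genes"])
    thresholds = QCThresholds(**(config.get("qc") or {}))
    gated, report = run_qc(bundle, thresholds)
    save_atlas(gated, outdir / "qc" / "atlas")
    write_results_table(report.pop("per_organ"), outdir / "qc" / "qc_per_organ.tsv")
    (outdir / "qc" / "qc_summary.json").write_text(json.dumps(report, indent=1))
    summary["qc"] = {"cells_out": gated.n_cells, "genes_out": gated.n_genes}


def _stage_composition(config: dict, outdir: Path, seed: int, summary: dict) -> None:
    bundle = _load_qc_bundle(outdir)
    cfg = config.get("composition") or {}
    alpha = float(cfg.get("alpha", 0.05))
    emap = hypergeometric_enrichment(bundle.cell_meta, cfg.get("row_var", "cell_type"),
                                     cfg.get("col_var", "organ"), alpha=alpha)
    write_results_table(emap.table, outdir / "composition" / "enrichment.tsv")
    pb = pseudobulk_profiles(bundle, cfg.get("group_by", "organ"))
    pb.reset_index().pipe(write_results_table, outdir / "composition" / "pseudobulk.tsv")
    corr = correlation_matrix(pb)
    corr.reset_index().pipe(write_results_table, outdir / "composition" / "correlation.tsv")
    freq = (bundle.cell_meta.groupby(["organ", "cell_type"], observed=True)
            .size().rename("n_cells").reset_index())
    write_results_table(freq, outdir / "composition" / "frequencies.tsv")
    summary["composition"] = {"n_groups": pb.shape[0]}


def _de_params(config: dict) -> DEParams:
    return DEParams(**(config.get("de") or {}))


def _stage_de(config: dict, outdir: Path, seed: int, summary: dict) -> None:
    bundle = _load_qc_bundle(outdir)
    p = _de_params(config)
    res = one_vs_rest_de(bundle, "organ", within="cell_type", min_cells=p.min_cells,
                         min_pct=p.min_pct, min_abs_log2fc=p.min_abs_log2fc, scale=p.scale)
    write_results_table(res.table, outdir / "de" / "de.tsv")
    write_results_table(res.comparisons, outdir / "de" / "comparisons.tsv")
    write_results_table(res.skipped, outdir / "de" / "skipped.tsv")
    summary["de"] = {"n_results": len(res.table), "n_comparisons": len(res.comparisons)}


def _stage_signatures(config: dict, outdir: Path, seed: int, summary: dict) -> None:
    bundle = _load_qc_bundle(outdir)
    screen = ScreenParams(**(config.get("screen") or {}))
    result = detect_organ_signatures(bundle, de_params=_de_params(config), screen_params=screen)
    write_results_table(result.table(), outdir / "signatures" / "signatures.tsv")
    write_results_table(signature_sharing(result), outdir / "signatures" / "sharing.tsv")
    write_results_table(result.analyzed, outdir / "signatures" / "analyzed.tsv")
    (outdir / "signatures" / "dendrograms.json").write_text(json.dumps(result.dendrograms, indent=1))
    summary["signatures"] = {"n_signatures": len(result.signatures),
                             "n_genes": int(len(result.table()))}


def _module_gene_set(config: dict, outdir: Path) -> GeneSet:
    cfg = config.get("scoring") or {}
    if cfg.get("gmt"):
        sets = read_gmt(cfg["gmt"])
        if not sets:
            raise PipelineError(f"no gene sets in {cfg['gmt']}")
        return sets[0]
    truth_path = _truth_path(outdir)
    if truth_path is None:
        raise PipelineError("score stage needs scoring.gmt or simulated ground truth")
    truth = GroundTruth.from_json(truth_path)
    if not truth.module_genes:
        raise PipelineError("ground truth has no module genes to score")
    return GeneSet("planted_module", tuple(truth.module_genes))


def _stage_score(config: dict, outdir: Path, seed: int, summary: dict) -> None:
    bundle = _load_qc_bundle(outdir)
    cfg = config.get("scoring") or {}
    gene_set = _module_gene_set(config, outdir)
    scores = ucell_score(bundle, gene_set, max_rank=int(cfg.get("max_rank", 1500)))
    out = scores.rename("ucell").reset_index()
    write_results_table(out, outdir / "score" / "ucell_scores.tsv")
    group_var = cfg.get("group_by", "organ")
    comparison = compare_group_scores(scores, bundle.cell_meta, group_var)
    write_results_table(comparison.group_stats, outdir / "score" / "group_stats.tsv")
    write_results_table(comparison.pairwise, outdir / "score" / "pairwise.tsv")
    summary["score"] = {"gene_set": gene_set.name, "n_groups": len(comparison.group_stats)}


def _gsea_sets(config: dict, outdir: Path, seed: int, de_table: pd.DataFrame) -> list[GeneSet]:
    cfg = config.get("gsea") or {}
    if cfg.get("gmt"):
        return read_gmt(cfg["gmt"])
    truth_path = _truth_path(outdir)
    if truth_path is None:
        raise PipelineError("gsea stage needs gsea.gmt or simulated ground truth")
    truth = GroundTruth.from_json(truth_path)
    if not truth.module_genes:
        raise PipelineError("ground truth has no module genes for gene sets")
    # planted module plus size-matched random control sets; controls are
    # drawn from genes that enter the DE-derived rankings at all, so they
    # can actually intersect the preranked lists
    rng = np.random.default_rng([seed, 4])
    universe = sorted(set(de_table["gene"].astype(str)))
    sets = [GeneSet("planted_module", tuple(truth.module_genes))]
    pool = [g for g in universe if g not in truth.module_genes]
    size = min(len(truth.module_genes), len(pool))
    for i in range(int(cfg.get("n_random_sets", 3))):
        if size == 0:
            break
        picked = rng.choice(len(pool), size=size, replace=False)
        sets.append(GeneSet(f"random_{i + 1}", tuple(pool[j] for j in picked)))
    return sets


def _stage_gsea(config: dict, outdir: Path, seed: int, summary: dict) -> None:
    de_path = outdir / "de" / "de.tsv"
    if not de_path.exists():
        raise PipelineError("missing dependency stage: de")
    cfg = config.get("gsea") or {}
    de_table = pd.read_csv(de_path, sep="\t")
    sets = _gsea_sets(config, outdir, seed, de_table)
    results: dict[tuple[str, str], pd.DataFrame] = {}
    frames = []
    pairs = de_table[["stratum", "group"]].drop_duplicates()
    for _, row in pairs.iterrows():
        ct, organ = str(row["stratum"]), str(row["group"])
        ranked = _ranking_from_de(de_table, ct, organ)
        if len(ranked) < int(cfg.get("min_size", 5)):
            continue
        # stable per-comparison sub-seed (process-independent)
        sub = int(hashlib.sha256(f"{seed}/{ct}/{organ}".encode()).hexdigest()[:8], 16) % (2 ** 31)
        res = preranked_gsea(ranked, sets, weight=float(cfg.get("weight", 1.0)),
                             n_perm=int(cfg.get("n_perm", 1000)),
                             seed=sub, min_size=int(cfg.get("min_size", 5)))
        results[(organ, ct)] = res
        frames.append(res.assign(organ=organ, cell_type=ct))
    enrichment = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame(columns=["set", "size", "es", "nes", "p_value",
                                             "q_value", "leading_edge", "organ", "cell_type"]))
    write_results_table(enrichment, outdir / "gsea" / "enrichment.tsv")
    if len({o for o, _ in results}) >= 2:
        uniq = pathway_uniqueness(results, q_threshold=float(cfg.get("q_threshold", 0.01)))
    else:
        uniq = pd.DataFrame(columns=["pathway", "enriched_in", "n_comparisons",
                                     "n_organs", "unique", "shared_3plus"])
    write_results_table(uniq, outdir / "gsea" / "uniqueness.tsv")
    summary["gsea"] = {"n_comparisons": len(results), "n_sets": len(sets)}


def _stage_report(config: dict, outdir: Path, seed: int, summary: dict) -> None:
    report: dict = {"seed": seed, "config_sha256": config_hash(config), "stages": {}}
    for stage in STAGES[:-1]:
        stage_dir = outdir / stage
        if stage_dir.exists():
            report["stages"][stage] = sorted(p.name for p in stage_dir.rglob("*") if p.is_file())
    (outdir / "report" / "report.json").write_text(json.dumps(report, indent=1))
    summary["report"] = {"stages_present": list(report["stages"])}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "composition": _stage_composition,
    "de": _stage_de,
    "signatures": _stage_signatures,
    "score": _stage_score,
    "gsea": _stage_gsea,
    "report": _stage_report,
}
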