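"""Synthetic multi-organ immune atlas generator with planted truths.

Counts follow a negative binomial model: the mean of gene g in a cell of
stratum (organ o, cell type c) is

    mu = baseline_g x organ_fold x cell_type_fold x module_fold x libsize,

with per-gene baselines drawn log-normally, a common NB dispersion, and
log-normal per-cell library-size factors.  Organ-specific effects are
multiplicative and applied only in the planted organ (optionally in a
subset of cell types); cell-type markers and an active gene module in
chosen strata are planted the same way.  CD45 (*PTPRC*) is detected in a
configurable fraction of cells, a small set of ``MT-`` genes carries a
controlled mitochondrial fraction, and deliberate QC violators (low-UMI
and high-mito cells) are injected so the gates are exercised.  All
planted assignments and per-cell labels are recorded in a
:class:`GroundTruth` for parameter-recovery testing.  Generation is fully
deterministic given the design seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atlas_io import AtlasBundle

logger = logging.getLogger(__name__)

_HIGH_MITO_RANGE = (0.18, 0.30)   # target fraction for injected high-mito violators
_LOW_UMI_TOTAL = 300.0            # expected total UMI of injected low-UMI violators


@dataclass(frozen=True)
class PlantedGene:
    """An organ-specific gene: over-expressed by ``fold`` in ``organ``.

    ``shared_cell_types`` restricts the effect to those cell types; the
    default (None) plants it across all cell types (a pan-cell-type
    organ gene such as a kidney GPX3 analogue).
    """

    gene: str
    organ: str
    fold: float
    shared_cell_types: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class MarkerGene:
    gene: str
    cell_type: str
    fold: float


@dataclass(frozen=True)
class ModuleActivation:
    organ: str
    cell_type: str
    fold: float


@dataclass
class SimulationDesign:
    """Study-condition parameters of the simulated atlas.

    Defaults emulate a small multi-organ immune compartment: four organs
    by three immune cell types at 150 cells per stratum, 1,000 genes,
    moderately over-dispersed UMI counts (NB dispersion theta = 2, i.e.
    var = mu + mu^2/2), per-gene log-normal baselines with median 2
    counts, 35% log-normal library-size spread, 2-8% mitochondrial
    content, 90% CD45+ cells, and 2% injected violators per QC rule.
    """

    organs: tuple[str, ...] = ("bone_marrow", "thymus", "kidney", "spleen")
    cell_types: tuple[str, ...] = ("T_NK", "B", "myeloid")
    cells_per_stratum: int | np.ndarray = 150
    n_genes: int = 1000
    baseline_mean: float = 2.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 2.0
    organ_specific: tuple[PlantedGene, ...] = ()
    cell_type_markers: tuple[MarkerGene, ...] = ()
    module_genes: tuple[str, ...] = ()
    module_active_strata: tuple[ModuleActivation, ...] = ()
    libsize_factor_sd: float = 0.35
    mito_fraction_range: tuple[float, float] = (0.02, 0.08)
    n_mito_genes: int = 5
    cd45_positive_fraction: float = 0.9
    frac_low_umi: float = 0.02
    frac_high_mito: float = 0.02
    seed: int = 0

    # -- derived ---------------------------------------------------------
    @property
    def n_organs(self) -> int:
        return len(self.organs)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def stratum_sizes(self) -> np.ndarray:
        """(n_organs, n_cell_types) integer matrix of cells per stratum."""
        sizes = np.asarray(self.cells_per_stratum)
        if sizes.ndim == 0:
            sizes = np.full((self.n_organs, self.n_cell_types), int(sizes))
        if sizes.shape != (self.n_organs, self.n_cell_types):
            raise ValueError(
                f"cells_per_stratum shape {sizes.shape} != "
                f"({self.n_organs}, {self.n_cell_types})"
            )
        return sizes.astype(int)

    def planted_gene_names(self) -> dict[str, list[str]]:
        return {
            "organ_specific": [p.gene for p in self.organ_specific],
            "markers": [m.gene for m in self.cell_type_markers],
            "module": list(self.module_genes),
        }

    def validate(self) -> None:
        sizes = self.stratum_sizes()
        if np.any(sizes < 0):
            raise ValueError("cells_per_stratum entries must be >= 0")
        if not (0 < self.cd45_positive_fraction <= 1):
            raise ValueError("cd45_positive_fraction must be in (0, 1]")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        groups = self.planted_gene_names()
        flat = groups["organ_specific"] + groups["markers"] + groups["module"]
        if len(set(groups["organ_specific"])) != len(groups["organ_specific"]):
            # one gene may be planted in several organs (a deliberate
            # non-unique plant); it still counts once in the universe
            pass
        union = set(groups["organ_specific"]) | set(groups["markers"]) | set(groups["module"])
        if (len(set(groups["organ_specific"])) + len(set(groups["markers"]))
                + len(set(groups["module"]))) != len(union):
            raise ValueError("planted gene lists must be pairwise disjoint")
        for p in self.organ_specific:
            if p.fold <= 1:
                raise ValueError(f"organ fold for {p.gene} must be > 1")
            if p.organ not in self.organs:
                raise ValueError(f"unknown organ {p.organ!r} for planted gene {p.gene}")
            cts = p.shared_cell_types or self.cell_types
            o = self.organs.index(p.organ)
            for ct in cts:
                if ct not in self.cell_types:
                    raise ValueError(f"unknown cell type {ct!r} for planted gene {p.gene}")
                if sizes[o, self.cell_types.index(ct)] == 0:
                    raise ValueError(
                        f"planted effect unobservable: stratum ({p.organ}, {ct}) is empty"
                    )
        for m in self.cell_type_markers:
            if m.fold <= 1:
                raise ValueError(f"marker fold for {m.gene} must be > 1")
            if m.cell_type not in self.cell_types:
                raise ValueError(f"unknown cell type {m.cell_type!r} for marker {m.gene}")
        for a in self.module_active_strata:
            if a.fold <= 1:
                raise ValueError("module activation fold must be > 1")
            if a.organ not in self.organs or a.cell_type not in self.cell_types:
                raise ValueError(f"unknown stratum ({a.organ}, {a.cell_type})")
            if sizes[self.organs.index(a.organ), self.cell_types.index(a.cell_type)] == 0:
                raise ValueError(
                    f"planted effect unobservable: stratum ({a.organ}, {a.cell_type}) is empty"
                )
        n_special = 1 + self.n_mito_genes + len(union)
        if self.n_genes < n_special + 10:
            raise ValueError(f"n_genes must be >= {n_special + 10} to fit planted genes")


@dataclass
class GroundTruth:
    """Realized planted parameters plus per-cell labels."""

    cells: pd.DataFrame  # barcode-indexed: organ, cell_type, module_active, qc_low_umi, qc_high_mito, cd45_positive
    organ_specific: list[dict]
    markers: list[dict]
    module_genes: list[str]
    module_active_strata: list[dict]

    def to_json(self, path) -> None:
        payload = {
            "organ_specific": self.organ_specific,
            "markers": self.markers,
            "module_genes": self.module_genes,
            "module_active_strata": self.module_active_strata,
            "cells": self.cells.reset_index().to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        cells = pd.DataFrame(payload["cells"]).set_index("barcode")
        return cls(cells, payload["organ_specific"], payload["markers"],
                   payload["module_genes"], payload["module_active_strata"])


def _gene_universe(design: SimulationDesign) -> tuple[list[str], list[str]]:
    """Gene name list: PTPRC, mito genes, planted genes, filler."""
    mito = [f"MT-SYN{i + 1}" for i in range(design.n_mito_genes)]
    groups = design.planted_gene_names()
    planted = list(dict.fromkeys(groups["organ_specific"] + groups["markers"] + groups["module"]))
    special = ["PTPRC", *mito, *planted]
    n_filler = design.n_genes - len(special)
    filler = [f"G{i + 1:05d}" for i in range(n_filler)]
    return special + filler, mito


def simulate_atlas(design: SimulationDesign) -> tuple[AtlasBundle, GroundTruth]:
    """Draw one atlas and its ground truth from a design (seeded)."""
    design.validate()
    gene_names, mito_genes = _gene_universe(design)
    name_to_idx = {g: j for j, g in enumerate(gene_names)}
    theta = design.nb_dispersion

    rng_base = np.random.default_rng([design.seed, 0])
    rng_counts = np.random.default_rng([design.seed, 1])
    rng_meta = np.random.default_rng([design.seed, 2])

    baseline = rng_base.lognormal(np.log(design.baseline_mean),
                                  design.baseline_log_sd, design.n_genes)
    groups = design.planted_gene_names()
    planted_all = set(groups["organ_specific"]) | set(groups["markers"]) | set(groups["module"])
    for g in planted_all:
        # planted markers are reliably expressed genes: upper half of the
        # baseline distribution
        baseline[name_to_idx[g]] = max(baseline[name_to_idx[g]], design.baseline_mean)
    # PTPRC and mito columns are overwritten below
    baseline[name_to_idx["PTPRC"]] = 0.0
    mito_idx = np.array([name_to_idx[g] for g in mito_genes])
    baseline[mito_idx] = 0.0

    sizes = design.stratum_sizes()
    blocks, meta_rows, truth_rows = [], [], []
    cell_counter = 0
    for o, organ in enumerate(design.organs):
        for c, ct in enumerate(design.cell_types):
            n = int(sizes[o, c])
            if n == 0:
                continue
            mu = baseline.copy()
            for p in design.organ_specific:
                cts = p.shared_cell_types or design.cell_types
                if p.organ == organ and ct in cts:
                    mu[name_to_idx[p.gene]] *= p.fold
            for m in design.cell_type_markers:
                if m.cell_type == ct:
                    mu[name_to_idx[m.gene]] *= m.fold
            module_active = False
            for a in design.module_active_strata:
                if a.organ == organ and a.cell_type == ct:
                    module_active = True
                    for g in design.module_genes:
                        mu[name_to_idx[g]] *= a.fold

            sd = design.libsize_factor_sd
            lib = rng_counts.lognormal(-sd ** 2 / 2.0, sd, n) if sd > 0 else np.ones(n)
            low_umi = rng_counts.random(n) < design.frac_low_umi
            expected_total = mu.sum()
            if expected_total > 0:
                lib[low_umi] = _LOW_UMI_TOTAL / expected_total

            mean = lib[:, None] * mu[None, :]
            with np.errstate(divide="ignore"):
                p_nb = theta / (theta + mean)
            counts = rng_counts.negative_binomial(theta, p_nb).astype(np.int64)

            # CD45 / PTPRC detection
            cd45_pos = rng_counts.random(n) < design.cd45_positive_fraction
            counts[:, name_to_idx["PTPRC"]] = np.where(
                cd45_pos, 1 + rng_counts.poisson(1.0, n), 0
            )

            # mitochondrial content: per-cell target fraction
            high_mito = rng_counts.random(n) < design.frac_high_mito
            lo, hi = design.mito_fraction_range
            frac = rng_counts.uniform(lo, hi, n)
            frac[high_mito] = rng_counts.uniform(*_HIGH_MITO_RANGE, int(high_mito.sum()))
            non_mito_total = counts.sum(axis=1).astype(float)
            mito_mean = frac / (1.0 - frac) * non_mito_total / design.n_mito_genes
            counts[:, mito_idx] = rng_counts.poisson(
                np.repeat(mito_mean[:, None], design.n_mito_genes, axis=1)
            )

            barcodes = [f"cell{cell_counter + i:06d}" for i in range(n)]
            cell_counter += n
            for i, bc in enumerate(barcodes):
                meta_rows.append({
                    "barcode": bc, "organ": organ, "cell_type": ct,
                    "sample_id": f"{organ}_s{1 + i % 2}", "project_id": f"proj_{organ}",
                    "doublet_score": float(rng_meta.uniform(0.0, 0.4)),
                })
                truth_rows.append({
                    "barcode": bc, "organ": organ, "cell_type": ct,
                    "module_active": module_active,
                    "qc_low_umi": bool(low_umi[i]), "qc_high_mito": bool(high_mito[i]),
                    "cd45_positive": bool(cd45_pos[i]),
                })
            blocks.append(sp.csr_matrix(counts))

    counts = sp.vstack(blocks, format="csr")
    cell_meta = pd.DataFrame(meta_rows).set_index("barcode")
    gene_table = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    gene_table["is_mito"] = [g.startswith("MT-") for g in gene_names]
    bundle = AtlasBundle(counts, cell_meta, gene_table)

    truth = GroundTruth(
        cells=pd.DataFrame(truth_rows).set_index("barcode"),
        organ_specific=[asdict(p) for p in design.organ_specific],
        markers=[asdict(m) for m in design.cell_type_markers],
        module_genes=list(design.module_genes),
        module_active_strata=[asdict(a) for a in design.module_active_strata],
    )
    return bundle, truth


def simulate_sorted_bulk(
    design: SimulationDesign,
    stratum: tuple[str, str],
    n_samples: int,
    seed: int = 0,
    depth_factor: float = 20.0,
) -> pd.DataFrame:
    """Pseudo-bulk NB profiles of one (organ, cell type) stratum.

    Emulates bulk RNA-seq of sorted cells from the stratum: samples are
    drawn from the stratum's generative means scaled by ``depth_factor``,
    so module genes are elevated iff the stratum is module-active.
    Returns a samples x genes table (empty for ``n_samples`` = 0).
    """
    design.validate()
    organ, ct = stratum
    if organ not in design.organs or ct not in design.cell_types:
        raise ValueError(f"unknown stratum ({organ!r}, {ct!r})")
    gene_names, _ = _gene_universe(design)
    name_to_idx = {g: j for j, g in enumerate(gene_names)}

    rng_base = np.random.default_rng([design.seed, 0])
    baseline = rng_base.lognormal(np.log(design.baseline_mean),
                                  design.baseline_log_sd, design.n_genes)
    groups = design.planted_gene_names()
    for g in set(groups["organ_specific"]) | set(groups["markers"]) | set(groups["module"]):
        baseline[name_to_idx[g]] = max(baseline[name_to_idx[g]], design.baseline_mean)
    baseline[name_to_idx["PTPRC"]] = design.baseline_mean  # sorted cells are CD45+
    mu = baseline.copy()
    for p in design.organ_specific:
        cts = p.shared_cell_types or design.cell_types
        if p.organ == organ and ct in cts:
            mu[name_to_idx[p.gene]] *= p.fold
    for m in design.cell_type_markers:
        if m.cell_type == ct:
            mu[name_to_idx[m.gene]] *= m.fold
    for a in design.module_active_strata:
        if a.organ == organ and a.cell_type == ct:
            for g in design.module_genes:
                mu[name_to_idx[g]] *= a.fold

    index = pd.Index([f"sample{i + 1}" for i in range(n_samples)], name="sample")
    if n_samples == 0:
        return pd.DataFrame(columns=gene_names, index=index)
    rng = np.random.default_rng([seed, design.seed, 3])
    sd = design.libsize_factor_sd
    lib = rng.lognormal(-sd ** 2 / 2.0, sd, n_samples) if sd > 0 else np.ones(n_samples)
    mean = depth_factor * lib[:, None] * mu[None, :]
    theta = design.nb_dispersion
    with np.errstate(divide="ignore"):
        p_nb = theta / (theta + mean)
    counts = rng.negative_binomial(theta, p_nb)
    return pd.DataFrame(counts, index=index, columns=gene_names)


def demo_design(
    seed: int = 0, cells_per_stratum: int = 150, n_genes: int = 1000
) -> SimulationDesign:
    """A compact demonstration design with all effect classes planted."""
    return SimulationDesign(
        organs=("bone_marrow", "thymus", "kidney", "spleen"),
        cell_types=("T_NK", "B", "myeloid"),
        cells_per_stratum=cells_per_stratum,
        n_genes=n_genes,
        organ_specific=(
            PlantedGene("GPX3s", "kidney", 6.0),
            PlantedGene("DNTTs", "thymus", 6.0),
            PlantedGene("ACVR2Bs", "thymus", 4.0),
        ),
        cell_type_markers=(
            MarkerGene("CD3Es", "T_NK", 6.0),
            MarkerGene("MS4A1s", "B", 6.0),
            MarkerGene("LYZs", "myeloid", 6.0),
        ),
        module_genes=tuple(f"NFKBT{i + 1:02d}" for i in range(20)),
        module_active_strata=(ModuleActivation("thymus", "B", 4.0),),
        seed=seed,
    )
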