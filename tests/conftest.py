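import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from immatlas import AtlasBundle, demo_design, run_qc, simulate_atlas


def make_bundle(counts, genes=None, organs=None, cell_types=None, **meta_cols):
    """Small hand-built bundle from a dense array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = genes or [f"g{j}" for j in range(n_genes)]
    meta = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n_cells)], name="barcode"))
    meta["organ"] = organs if organs is not None else ["organ_a"] * n_cells
    if cell_types is not None:
        meta["cell_type"] = cell_types
    for k, v in meta_cols.items():
        meta[k] = v
    gene_table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    return AtlasBundle(sp.csr_matrix(counts), meta, gene_table)


@pytest.fixture(scope="session")
def demo_atlas():
    """One simulated demo atlas with planted organ genes, markers and module."""
    bundle, truth = simulate_atlas(demo_design(seed=7))
    return bundle, truth


@pytest.fixture(scope="session")
def demo_qc(demo_atlas):
    bundle, truth = demo_atlas
    gated, report = run_qc(bundle)
    return gated, truth
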