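import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from myelotrace import synthetic_data as sd
from myelotrace.io_formats import CellAtlas


@pytest.fixture(scope="session")
def small_config() -> sd.SimConfig:
    """A compact two-tissue configuration for fast unit tests."""
    return sd.SimConfig(
        seed=11,
        tissues=("blood", "cortex"),
        subgroup_spec={
            "blood": {"Ly6c+.Mon": 40, "B.cells": 40},
            "cortex": {"MG": 40, "aMG": 40},
        },
        n_genes=120,
        marker_spec={
            "Ly6c+.Mon": [("Ccr2", 2.0)],
            "MG": [("P2ry12", 3.0), ("Tmem119", 3.0)],
            "aMG": [("Apoe", 3.0), ("Ccl2", 1.0)],
        },
        condition_effects=[
            sd.ConditionEffect("Ccl2", "cortex", "aMG", "24h", 1.5),
        ],
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    atlas, truth = sd.generate_atlas(small_config)
    return atlas, truth


@pytest.fixture(scope="session")
def traj_data():
    """Three-branch trajectory dataset with six planted gene programs."""
    cfg = sd.SimConfig(seed=3, n_genes=200)
    spec = sd.three_branch_spec(n_cells=200, genes_per_program=8, lfc=2.0)
    atlas, truth = sd.generate_trajectory_data(cfg, spec)
    return atlas, truth


@pytest.fixture
def toy_atlas() -> CellAtlas:
    """3 genes x 3 cells with a mitochondrial gene, fully hand-checkable."""
    counts = sp.csr_matrix(
        np.array(
            [
                [5, 0, 2],   # mt-Toy
                [0, 0, 1],
                [3, 0, 4],
            ]
        )
    )
    gene_meta = pd.DataFrame(
        {"mito": [True, False, False]},
        index=pd.Index(["mt-Toy", "GeneA", "GeneB"], name="symbol"),
    )
    cell_meta = pd.DataFrame(
        {
            "tissue": ["cortex"] * 3,
            "subgroup": ["MG", "MG", "aMG"],
            "condition": ["TBI", "Sham", "Sham"],
            "timepoint": ["24h", "24h", "7d"],
            "mouse": ["m1", "m2", "m3"],
        },
        index=pd.Index(["c1", "c2", "c3"], name="barcode"),
    )
    return CellAtlas(counts=counts, gene_meta=gene_meta, cell_meta=cell_meta)
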