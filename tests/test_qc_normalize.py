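import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from myelotrace import qc_normalize as qcn
from myelotrace.io_formats import CellAtlas


def _random_atlas(seed, n_genes=60, n_cells=100, mito=5):
    rng = np.random.default_rng(seed)
    counts = sp.csr_matrix(rng.poisson(1.0, size=(n_genes, n_cells)))
    names = [f"mt-{i}" if i < mito else f"G{i}" for i in range(n_genes)]
    gene_meta = pd.DataFrame(
        {"mito": [n.startswith("mt-") for n in names]},
        index=pd.Index(names, name="symbol"),
    )
    return CellAtlas(counts=counts, gene_meta=gene_meta)


class TestCellQC:
    def test_hand_checked_cell(self, toy_atlas):
        qc = qcn.compute_cell_qc(toy_atlas)
        # cell c1: counts (5, 0, 3), gene 1 mito -> detected 2, mito 5/8
        row = qc.table.loc["c1"]
        assert row["detected_genes"] == 2
        assert row["mito_fraction"] == pytest.approx(5 / 8)
        assert row["total_counts"] == 8

    def test_all_zero_cell_defined_as_zero(self, toy_atlas):
        qc = qcn.compute_cell_qc(toy_atlas)
        assert qc.table.loc["c2", "detected_genes"] == 0
        assert qc.table.loc["c2", "mito_fraction"] == 0.0

    def test_matches_brute_force_recomputation(self):
        atlas = _random_atlas(0)
        qc = qcn.compute_cell_qc(atlas).table
        dense = np.asarray(atlas.counts.todense())
        mito = atlas.gene_meta["mito"].to_numpy()
        for j in range(atlas.n_cells):
            col = dense[:, j]
            assert qc["detected_genes"].iloc[j] == int((col > 0).sum())
            total = col.sum()
            expect = col[mito].sum() / total if total else 0.0
            assert qc["mito_fraction"].iloc[j] == pytest.approx(expect)


class TestFilterCells:
    @staticmethod
    def _atlas_with_qc(cells):
        """cells: list of (n_detected_nonmito, mito_count) built exactly.

        Gene 0 is the only mitochondrial gene; each cell expresses
        ``n_detected_nonmito`` distinct non-mito genes at count 1 plus
        ``mito_count`` reads of gene 0, so detected genes and mito fraction
        are exact by construction.
        """
        n_genes = 7000
        cols = []
        for n_det, n_mito in cells:
            col = np.zeros(n_genes)
            col[1 : 1 + n_det] = 1
            col[0] = n_mito
            cols.append(col)
        counts = sp.csr_matrix(np.array(cols).T)
        names = ["mt-1"] + [f"G{i}" for i in range(n_genes - 1)]
        gene_meta = pd.DataFrame(
            {"mito": [n.startswith("mt-") for n in names]}, index=names
        )
        return CellAtlas(counts=counts, gene_meta=gene_meta)

    def test_boundary_cells_retained_interior_removed(self):
        # detected counts: 200 (kept), 199 (low), 6000 (kept), 6001 (high);
        # mito fractions: 30/300 = 0.10 exactly (kept), 45/300 = 0.15 (out)
        atlas = self._atlas_with_qc(
            [(200, 0), (199, 0), (6000, 0), (6001, 0), (270, 30), (255, 45)]
        )
        qc = qcn.compute_cell_qc(atlas)
        det = qc.table["detected_genes"].to_numpy()
        mito = qc.table["mito_fraction"].to_numpy()
        assert det.tolist() == [200, 199, 6000, 6001, 271, 256]
        assert mito[4] == pytest.approx(30 / 300) and mito[5] == pytest.approx(45 / 300)
        kept = qcn.filter_cells(atlas, qc)
        assert kept.n_cells == 3
        kept_detected = qcn.compute_cell_qc(kept).table["detected_genes"]
        assert sorted(kept_detected) == [200, 271, 6000]

    def test_idempotent(self):
        atlas = _random_atlas(1)
        once = qcn.filter_cells(atlas, min_genes=10, max_genes=50, max_mito=0.2)
        twice = qcn.filter_cells(once, min_genes=10, max_genes=50, max_mito=0.2)
        assert once.n_cells == twice.n_cells

    def test_random_fixture_equals_predicate_evaluation(self):
        atlas = _random_atlas(2)
        qc = qcn.compute_cell_qc(atlas)
        kept = qcn.filter_cells(atlas, qc, min_genes=20, max_genes=40,
                                max_mito=0.15)
        t = qc.table
        expect = (
            (t["detected_genes"] >= 20)
            & (t["detected_genes"] <= 40)
            & (t["mito_fraction"] <= 0.15)
        ).to_numpy()
        assert kept.n_cells == int(expect.sum())

    def test_no_survivors_is_an_error(self):
        atlas = _random_atlas(3)
        with pytest.raises(ValueError, match="no cells"):
            qcn.filter_cells(atlas, min_genes=5000, max_genes=6000)


class TestLogNormalize:
    def test_zero_stays_zero_and_hand_value(self):
        counts = sp.csr_matrix(np.array([[10], [9990], [0]]))
        atlas = CellAtlas(
            counts=counts,
            gene_meta=pd.DataFrame({"mito": [False] * 3},
                                   index=["A", "B", "C"]),
        )
        norm = qcn.log_normalize(atlas, scale=1e4)
        dense = np.asarray(norm.todense())
        # count 10 of total 10,000 at scale 1e4 -> ln(11)
        assert dense[0, 0] == pytest.approx(np.log(11.0), abs=1e-12)
        assert dense[2, 0] == 0.0

    def test_depth_rescaling_invariance(self):
        atlas = _random_atlas(4)
        doubled = CellAtlas(counts=atlas.counts * 2, gene_meta=atlas.gene_meta)
        a = np.asarray(qcn.log_normalize(atlas).todense())
        b = np.asarray(qcn.log_normalize(doubled).todense())
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestVariableGenes:
    def test_planted_high_variance_genes_recovered(self):
        rng = np.random.default_rng(5)
        n_genes, n_cells = 200, 300
        # background genes span a range of means so the mean-variance trend
        # is anchored around the planted genes' expression level
        rates = rng.lognormal(1.0, 1.0, size=n_genes)
        base = rng.poisson(rates[:, None], size=(n_genes, n_cells)).astype(float)
        # 10 bimodal genes: strongly on in half the cells, off otherwise
        for i in range(10):
            base[i, :] = 0.0
            base[i, : n_cells // 2] = rng.poisson(30.0, size=n_cells // 2)
        names = [f"HV{i}" if i < 10 else f"G{i}" for i in range(n_genes)]
        atlas = CellAtlas(
            counts=sp.csr_matrix(base),
            gene_meta=pd.DataFrame({"mito": [False] * n_genes}, index=names),
        )
        top = qcn.select_variable_genes(atlas, n=20)
        assert set(f"HV{i}" for i in range(10)) <= set(top)

    def test_zero_variance_gene_ranks_last(self):
        atlas = _random_atlas(6)
        counts = np.asarray(atlas.counts.todense())
        counts[10, :] = 3  # constant gene
        atlas = CellAtlas(counts=sp.csr_matrix(counts),
                          gene_meta=atlas.gene_meta)
        ranked = qcn.select_variable_genes(atlas, n=atlas.n_genes)
        assert ranked.index(atlas.gene_names[10]) >= atlas.n_genes - 10

    def test_requesting_too_many_errors(self):
        atlas = _random_atlas(7)
        with pytest.raises(ValueError):
            qcn.select_variable_genes(atlas, n=atlas.n_genes + 1)


class TestPCA:
    def test_variance_ordering_and_determinism(self):
        atlas = _random_atlas(8)
        norm = qcn.log_normalize(
            qcn.filter_cells(atlas, min_genes=1, max_genes=10**6, max_mito=1.0)
        )
        genes = list(atlas.gene_names[:40])
        emb1 = qcn.scale_and_pca(norm, atlas.gene_names, genes, n_pcs=5)
        emb2 = qcn.scale_and_pca(norm, atlas.gene_names, genes, n_pcs=5)
        np.testing.assert_array_equal(emb1, emb2)
        var = emb1.var(axis=0)
        assert np.all(np.diff(var) <= 1e-9)

    def test_two_subgroups_separable_on_pc1(self, small_atlas):
        from sklearn.metrics import silhouette_score

        atlas, _ = small_atlas
        cortex = atlas.subset_cells(
            atlas.cell_meta["tissue"].to_numpy() == "cortex"
        )
        norm = qcn.log_normalize(cortex)
        hvg = qcn.select_variable_genes(cortex, n=50)
        emb = qcn.scale_and_pca(norm, cortex.gene_names, hvg, n_pcs=2)
        labels = cortex.cell_meta["subgroup"].to_numpy()
        assert silhouette_score(emb[:, :1], labels) > 0
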