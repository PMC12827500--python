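import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from myelotrace import qc_normalize as qcn
from myelotrace import synthetic_data as sd
from myelotrace import trajectory as traj


def brute_force_mst_weight(points: np.ndarray) -> float:
    """Minimum spanning-tree weight by exhaustive enumeration over all
    labeled trees (Prüfer sequences)."""
    n = len(points)
    dist = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    if n == 1:
        return 0.0
    if n == 2:
        return float(dist[0, 1])
    best = np.inf
    for pruefer in itertools.product(range(n), repeat=n - 2):
        degree = np.ones(n, dtype=int)
        for v in pruefer:
            degree[v] += 1
        seq = list(pruefer)
        weight = 0.0
        deg = degree.copy()
        ptr_nodes = set(range(n))
        for v in seq:
            leaf = min(u for u in ptr_nodes if deg[u] == 1)
            weight += dist[leaf, v]
            deg[leaf] -= 1
            deg[v] -= 1
            ptr_nodes.discard(leaf)
        u, w = sorted(u for u in ptr_nodes if deg[u] == 1)
        weight += dist[u, w]
        best = min(best, weight)
    return best


def matched_accuracy(truth, pred) -> float:
    """Best label-matching accuracy over permutations of predicted labels."""
    t_labels = sorted(set(truth))
    p_labels = sorted(set(pred))
    best = 0.0
    for perm in itertools.permutations(p_labels, len(t_labels)):
        m = dict(zip(t_labels, perm))
        best = max(best, float(np.mean([m[t] == p for t, p in zip(truth, pred)])))
    return best


class TestMST:
    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (4, 3)])
    def test_mst_matches_exhaustive_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(n, 2))
        edges = traj._mst_edges(pts)
        weight = sum(np.linalg.norm(pts[u] - pts[v]) for u, v in edges)
        assert len(edges) == n - 1
        assert weight == pytest.approx(brute_force_mst_weight(pts), rel=1e-9)


class TestFitTrajectory:
    def test_three_branch_recovery(self, traj_data):
        atlas, truth = traj_data
        emb = truth.cell_labels[["x", "y"]].to_numpy()
        model = traj.fit_trajectory(
            emb, atlas.cell_meta["subgroup"].to_numpy(), "Ly6c+.Mon",
            k_centroids=25,
        )
        assert model.n_states == 3
        acc = matched_accuracy(
            truth.cell_labels["branch"].to_numpy(), model.cell_state
        )
        assert acc >= 0.8

    def test_pseudotime_root_minimal_and_nonnegative(self, traj_data):
        atlas, truth = traj_data
        emb = truth.cell_labels[["x", "y"]].to_numpy()
        model = traj.fit_trajectory(
            emb, atlas.cell_meta["subgroup"].to_numpy(), "Ly6c+.Mon",
            k_centroids=25,
        )
        assert model.pseudotime.min() >= 0
        root_cells = model.cell_centroid == model.root
        assert model.pseudotime[root_cells].mean() < model.pseudotime.mean()
        # monocytes sit at the root end
        mon = atlas.cell_meta["subgroup"].to_numpy() == "Ly6c+.Mon"
        assert model.pseudotime[mon].mean() < model.pseudotime[~mon].mean()

    def test_linear_data_single_state_ordering(self):
        cfg = sd.SimConfig(seed=7, n_genes=120)
        spec = [sd.BranchSpec("A", None, 20.0, 400, {"Gene0001": 2.0},
                              "Ly6c+.Mon")]
        atlas, truth = sd.generate_trajectory_data(cfg, spec)
        emb = truth.cell_labels[["x", "y"]].to_numpy()
        model = traj.fit_trajectory(
            emb, atlas.cell_meta["subgroup"].to_numpy(), "Ly6c+.Mon",
            k_centroids=15,
        )
        assert model.n_states == 1
        rho = sps.spearmanr(
            model.pseudotime, truth.cell_labels["true_order"]
        ).statistic
        assert rho >= 0.9

    def test_degenerate_embedding_errors(self):
        X = np.zeros((50, 2))
        with pytest.raises(ValueError, match="degenerate"):
            traj.fit_trajectory(X, ["a"] * 50, "a", k_centroids=5)

    def test_missing_root_subgroup_errors(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        with pytest.raises(ValueError, match="root"):
            traj.fit_trajectory(X, ["a"] * 50, "b", k_centroids=5)


@pytest.fixture(scope="module")
def fitted(traj_data):
    atlas, truth = traj_data
    emb = truth.cell_labels[["x", "y"]].to_numpy()
    model = traj.fit_trajectory(
        emb, atlas.cell_meta["subgroup"].to_numpy(), "Ly6c+.Mon",
        k_centroids=25,
    )
    norm = qcn.log_normalize(atlas)
    result = traj.branch_dependent_genes(norm, atlas.gene_names, model)
    return atlas, truth, model, result


class TestBranchGenes:
    def test_anova_f_matches_hand_computation(self):
        # groups (1,2,3), (2,3,4), (6,7,8): SSB computed by textbook formula
        x = np.array([[1, 2, 3, 2, 3, 4, 6, 7, 8]], dtype=float)
        states = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        model = traj.TrajectoryModel(
            embedding=None, centroids=None, edges=None, root=0,
            cell_centroid=None, cell_state=states,
            pseudotime=np.zeros(9),
        )
        res = traj.branch_dependent_genes(x, ["g"], model)
        f_ref, p_ref = sps.f_oneway(x[0, :3], x[0, 3:6], x[0, 6:])
        assert res["F"].iloc[0] == pytest.approx(f_ref, rel=1e-10)
        assert res["pvalue"].iloc[0] == pytest.approx(p_ref, rel=1e-10)
        # hand: group means 2,3,7; grand 4; SSB=3*(4+1+9)=42; SSW=6
        assert res["F"].iloc[0] == pytest.approx((42 / 2) / (6 / 6), rel=1e-12)

    def test_constant_gene_not_significant(self, fitted):
        atlas, truth, model, result = fitted
        x = np.vstack([np.ones(model.cell_state.size), np.ones(model.cell_state.size)])
        res = traj.branch_dependent_genes(x, ["c1", "c2"], model)
        assert (res["pvalue"] == 1.0).all()
        assert not res["significant"].any()

    def test_planted_program_sensitivity(self, fitted):
        atlas, truth, model, result = fitted
        planted = set(truth.gene_programs)
        sig = set(result.index[result["significant"]])
        sensitivity = len(planted & sig) / len(planted)
        assert sensitivity >= 0.9

    def test_single_state_errors(self):
        model = traj.TrajectoryModel(
            embedding=None, centroids=None, edges=None, root=0,
            cell_centroid=None, cell_state=np.ones(10, dtype=int),
            pseudotime=np.zeros(10),
        )
        with pytest.raises(ValueError, match="2 states"):
            traj.branch_dependent_genes(np.ones((2, 10)), ["a", "b"], model)


class TestClusterBranchGenes:
    @pytest.fixture
    def result(self, fitted):
        _, truth, _, res = fitted
        return truth, res

    def test_six_planted_programs_recovered(self, result):
        truth, res = result
        labels = traj.cluster_branch_genes(res, k=6)
        prog = [g for g in labels.index if g in truth.gene_programs]
        ari = adjusted_rand_score(
            [truth.gene_programs[g] for g in prog], labels.loc[prog]
        )
        assert ari >= 0.8

    def test_k_one_single_subgroup(self, result):
        _, res = result
        labels = traj.cluster_branch_genes(res, k=1)
        assert set(labels) == {1}

    def test_gene_order_invariance(self, result):
        _, res = result
        shuffled = res.sample(frac=1.0, random_state=0)
        a = traj.cluster_branch_genes(res, k=6).sort_index()
        b = traj.cluster_branch_genes(shuffled, k=6).sort_index()
        pd.testing.assert_series_equal(a, b)

    def test_too_few_significant_genes_errors(self, result):
        _, res = result
        tiny = res.iloc[:3]
        with pytest.raises(ValueError, match="k"):
            traj.cluster_branch_genes(tiny, k=6)


def test_gene_universe_intersection_preserves_order():
    out = traj.intersect_gene_universe([["c", "a", "b"], ["b", "c"], ["c", "b", "x"]])
    assert out == ["c", "b"]
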