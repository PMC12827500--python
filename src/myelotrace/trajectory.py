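"""Branching pseudotime over a minimum-spanning-tree backbone.

A deliberately simple surrogate for reversed-graph-embedding trajectory
tools: k-means centroids summarize the embedding, a Euclidean MST over the
centroids gives the tree, the root is the leaf richest in the designated
root subgroup (monocytes, in the myeloid analysis), states are maximal
unbranched segments walking from the root, and pseudotime is geodesic
distance along the tree plus a projection offset onto the local edge.  The
observable contract — a small number of states, a root, a cell ordering, and
branch-dependent genes — matches what branched-heatmap analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as _sps
from scipy.cluster import hierarchy
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .stats_core import bh_adjust

__all__ = ["TrajectoryModel", "fit_trajectory", "branch_dependent_genes",
           "cluster_branch_genes", "intersect_gene_universe"]


@dataclass
class TrajectoryModel:
    embedding: np.ndarray          # cells x 2
    centroids: np.ndarray          # k x 2
    edges: list[tuple[int, int]]   # spanning-tree edges over centroids
    root: int
    cell_centroid: np.ndarray      # per-cell nearest centroid id
    cell_state: np.ndarray         # per-cell state id (1-based)
    pseudotime: np.ndarray         # per-cell, >= 0, root cells minimal
    centroid_state: np.ndarray = field(default=None)
    n_states: int = 0


def intersect_gene_universe(gene_lists: list[list[str]]) -> list[str]:
    """Overlapping features across tissues, in the order of the first list."""
    if not gene_lists:
        return []
    common = set(gene_lists[0])
    for gl in gene_lists[1:]:
        common &= set(gl)
    return [g for g in gene_lists[0] if g in common]


def _mst_edges(centroids: np.ndarray) -> list[tuple[int, int]]:
    d = squareform(
        np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)),
        checks=False,
    )
    dense = squareform(d)
    mst = minimum_spanning_tree(dense)
    rows, cols = mst.nonzero()
    return [(int(min(u, v)), int(max(u, v))) for u, v in zip(rows, cols)]


def _adjacency(k: int, edges) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(k)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    return adj


def _geodesics(centroids, adj, start):
    """BFS tree distances and parents from ``start`` along weighted edges."""
    k = len(adj)
    dist = np.full(k, np.inf)
    parent = np.full(k, -1)
    dist[start] = 0.0
    frontier = [start]
    seen = {start}
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    parent[v] = u
                    dist[v] = dist[u] + np.linalg.norm(
                        centroids[u] - centroids[v]
                    )
                    nxt.append(v)
        frontier = nxt
    return dist, parent


def _prune_short_leaves(centroids: np.ndarray, min_length_frac: float):
    """Drop MST leaf segments shorter than a fraction of the tree diameter.

    Noisy embeddings produce short spurious side-branches off the backbone;
    removing them (one shortest segment per round, re-deriving the MST) is
    what turns the raw MST into the small-state-count tree the analysis
    expects.  Returns the surviving centroid array and its MST edges.
    """
    alive = np.arange(len(centroids))
    while True:
        cents = centroids[alive]
        edges = _mst_edges(cents)
        k = len(alive)
        if k <= 3:
            return cents, edges
        adj = _adjacency(k, edges)
        degree = np.array([len(a) for a in adj])
        branch_nodes = np.flatnonzero(degree >= 3)
        if branch_nodes.size == 0:
            return cents, edges
        # tree diameter via double sweep
        d0, _ = _geodesics(cents, adj, 0)
        far = int(np.argmax(d0))
        d1, _ = _geodesics(cents, adj, far)
        diameter = float(d1.max())
        threshold = min_length_frac * diameter
        # leaf segments: path from each leaf to its first branch node
        worst, worst_len = None, np.inf
        for leaf in np.flatnonzero(degree == 1):
            seg, node, prev = [leaf], leaf, -1
            length = 0.0
            while degree[node] < 3:
                nbrs = [v for v in adj[node] if v != prev]
                if not nbrs:
                    break
                prev, node = node, nbrs[0]
                length += float(np.linalg.norm(cents[seg[-1]] - cents[node]))
                if degree[node] < 3:
                    seg.append(node)
            if length < threshold and length < worst_len:
                worst, worst_len = seg, length
        if worst is None:
            return cents, edges
        alive = alive[np.setdiff1d(np.arange(k), worst)]


def fit_trajectory(
    embedding: np.ndarray,
    subgroups,
    root_subgroup: str,
    k_centroids: int = 25,
    random_state: int = 0,
    prune_min_length_frac: float = 0.15,
) -> TrajectoryModel:
    """Fit the MST trajectory surrogate on a 2-D embedding.

    k-means centroids (seeded), Euclidean MST, and pruning of leaf segments
    shorter than ``prune_min_length_frac`` of the tree diameter (spurious
    noise branches).  ``subgroups`` are per-cell labels used only to pick the
    root: among degree-1 tree nodes, the one whose assigned cells have the
    highest fraction of ``root_subgroup`` (ties broken by lower centroid id).
    States are maximal unbranched tree segments walking out from the root;
    pseudotime is tree-geodesic distance from the root centroid to the
    orthogonal projection of the cell onto its best incident edge.
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("embedding must be cells x 2")
    subgroups = np.asarray(subgroups)
    if subgroups.shape[0] != X.shape[0]:
        raise ValueError("subgroups length must match embedding")
    if root_subgroup not in set(subgroups):
        raise ValueError(f"root subgroup {root_subgroup!r} not present")
    if X.shape[0] < k_centroids:
        raise ValueError(f"need >= {k_centroids} cells, got {X.shape[0]}")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate embedding: all points identical")

    km = KMeans(n_clusters=k_centroids, random_state=random_state, n_init=10)
    km.fit(X)
    centroids, edges = _prune_short_leaves(
        km.cluster_centers_, prune_min_length_frac
    )
    k = len(centroids)
    # assign cells to the nearest surviving centroid
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    cell_centroid = np.argmin(d2, axis=1)

    adj = _adjacency(k, edges)
    degree = np.array([len(a) for a in adj])

    # root: degree-1 node with highest root-subgroup fraction; tie -> lower id
    leaves = np.flatnonzero(degree == 1)
    if leaves.size == 0:  # k == 1
        leaves = np.array([0])
    best, best_frac = None, -1.0
    for leaf in leaves:
        cells = cell_centroid == leaf
        frac = (
            float(np.mean(subgroups[cells] == root_subgroup)) if cells.any() else 0.0
        )
        if frac > best_frac:
            best, best_frac = int(leaf), frac
    root = best

    dist, parent = _geodesics(centroids, adj, root)
    if np.isinf(dist).any():
        raise ValueError("centroid tree is disconnected")

    # states: maximal unbranched segments from the root; children of a
    # branch point (tree degree >= 3, or the root with several children)
    # each start a new state
    centroid_state = np.zeros(k, dtype=int)
    next_state = 1
    children: list[list[int]] = [[] for _ in range(k)]
    for v in range(k):
        if parent[v] >= 0:
            children[parent[v]].append(v)
    stack = [(root, 0)]  # (node, inherited state; 0 = start new)
    while stack:
        node, state = stack.pop()
        if state == 0:
            state = next_state
            next_state += 1
        centroid_state[node] = state
        kids = children[node]
        branching = len(kids) >= 2
        for kid in sorted(kids, reverse=True):
            stack.append((kid, 0 if branching else state))
    n_states = next_state - 1

    # pseudotime: project each cell onto incident edges of its centroid,
    # pick the projection nearest the cell, clamp to the edge
    pseudotime = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        c = cell_centroid[i]
        best_pt, best_res = dist[c], np.inf
        for nbr in adj[c]:
            u, v = (nbr, c) if dist[nbr] < dist[c] else (c, nbr)
            seg = centroids[v] - centroids[u]
            seg_len = np.linalg.norm(seg)
            if seg_len == 0:
                continue
            t = float(np.dot(X[i] - centroids[u], seg) / seg_len**2)
            t = min(max(t, 0.0), 1.0)
            proj = centroids[u] + t * seg
            res = np.linalg.norm(X[i] - proj)
            if res < best_res:
                best_res = res
                best_pt = dist[u] + t * seg_len
        pseudotime[i] = best_pt

    cell_state = centroid_state[cell_centroid]
    return TrajectoryModel(
        embedding=X,
        centroids=centroids,
        edges=edges,
        root=root,
        cell_centroid=cell_centroid,
        cell_state=cell_state,
        pseudotime=pseudotime,
        centroid_state=centroid_state,
        n_states=n_states,
    )


def branch_dependent_genes(
    norm: sp.spmatrix | np.ndarray,
    gene_names,
    model: TrajectoryModel,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA of normalized expression across states.

    Returns a DataFrame indexed by gene with the F statistic, raw and
    BH-adjusted p, per-state mean profile columns (``mean_state_<s>``) and a
    ``significant`` flag at adjusted p < ``alpha``.  Genes constant across
    all cells get F = 0, p = 1.
    """
    states = np.unique(model.cell_state)
    if states.size < 2:
        raise ValueError("branch-dependent testing needs >= 2 states")
    X = np.asarray(sp.csr_matrix(norm).todense(), dtype=float)
    if X.shape[1] != model.cell_state.size:
        raise ValueError("matrix cells do not match trajectory model")
    n = X.shape[1]
    k = states.size

    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    means = {}
    for s in states:
        mask = model.cell_state == s
        ns = int(mask.sum())
        mu_s = X[:, mask].mean(axis=1)
        means[s] = mu_s
        ssb += ns * (mu_s - grand) ** 2
        ssw += ((X[:, mask] - mu_s[:, None]) ** 2).sum(axis=1)

    df_b, df_w = k - 1, n - k
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    p = np.where(
        ssw > 0,
        _sps.f.sf(np.where(ssw > 0, F, 0.0), df_b, df_w),
        np.where(ssb > 0, 0.0, 1.0),
    )
    F = np.where(ssw > 0, F, np.where(ssb > 0, np.inf, 0.0))
    p_adj = bh_adjust(p)

    out = pd.DataFrame(
        {"F": F, "pvalue": p, "p_adj": p_adj},
        index=pd.Index(list(gene_names), name="gene"),
    )
    for s in states:
        out[f"mean_state_{s}"] = means[s]
    out["significant"] = out["p_adj"] < alpha
    return out


def cluster_branch_genes(result: pd.DataFrame, k: int = 6) -> pd.Series:
    """Group significant branch-dependent genes into k expression subgroups.

    Ward-linkage hierarchical clustering (Euclidean) of row-standardized
    state-mean profiles, cut at ``k``; subgroup ids follow dendrogram leaf
    order so the labeling is deterministic and invariant to input gene
    order.  Returns a gene -> subgroup (1..k) Series.
    """
    sig = result[result["significant"]].sort_index(kind="stable")
    profile_cols = [c for c in result.columns if c.startswith("mean_state_")]
    if len(sig) < k:
        raise ValueError(
            f"only {len(sig)} significant genes; choose k <= {len(sig)}"
        )
    P = sig[profile_cols].to_numpy(dtype=float)
    mu = P.mean(axis=1, keepdims=True)
    sd = P.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (P - mu) / sd
    if k == 1:
        labels = np.ones(len(sig), dtype=int)
    else:
        link = hierarchy.linkage(Z, method="ward")
        raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
        # relabel by dendrogram leaf order for determinism
        leaf_order = hierarchy.leaves_list(link)
        mapping: dict[int, int] = {}
        for leaf in leaf_order:
            mapping.setdefault(raw[leaf], len(mapping) + 1)
        labels = np.array([mapping[r] for r in raw])
    return pd.Series(labels, index=sig.index, name="gene_subgroup")
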