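"""Gene-set over-representation and per-cell pathway activity scoring.

ORA is the upper-tail hypergeometric test of query/set overlap against a
gene universe, BH-corrected across sets.  Pathway activity is a rank-based
single-sample random-walk score in the ssGSEA/GSVA family: walking down the
expression-ranked gene list, the running sum steps up (rank-weighted) at set
members and down elsewhere; the score is the sum of the maximum and minimum
deviations, which lies in [-1, 1].  Being rank-based, scores are invariant
to any monotone per-cell transform of expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom

from .stats_core import bh_adjust, student_t

__all__ = ["ora", "gsva_like", "compare_activity"]


def ora(
    query: list[str],
    universe: list[str],
    genesets: dict[str, list[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe; p = P(X >= overlap) for
    X ~ Hypergeom(universe, set, query); BH adjustment across all tested
    sets, significant iff adjusted p < ``alpha``.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("universe is empty")
    uni_set = set(uni)
    q = [g for g in dict.fromkeys(query)]
    if not q:
        raise ValueError("query is empty")
    stray = [g for g in q if g not in uni_set]
    if stray:
        raise ValueError(f"query genes outside universe: {stray[:5]}")
    if not genesets:
        raise ValueError("no gene sets supplied")

    M, N = len(uni), len(q)
    qset = set(q)
    rows = []
    for name, members in genesets.items():
        mem = set(members) & uni_set
        K = len(mem)
        k = len(mem & qset)
        p = float(hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append(
            {
                "geneset": name,
                "overlap": k,
                "query_size": N,
                "set_size": K,
                "universe_size": M,
                "pvalue": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("geneset")
    out["p_adj"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def gsva_like(
    expr: np.ndarray | sp.spmatrix,
    gene_names,
    genesets: dict[str, list[str]],
    tau: float = 1.0,
) -> pd.DataFrame:
    """Per-cell rank-based activity score for each gene set.

    ``expr`` is genes x cells on a log scale (any monotone scale gives the
    same result).  Per cell, genes are ranked by decreasing expression (ties
    broken by stable gene order; the most-expressed gene has rank n_genes).
    Walking down the ranking, the running sum steps up by rank**tau
    normalized over member ranks at member genes and down by
    1/(n_genes - n_members) otherwise; the score is max + min of the running
    sum.  A set covering every gene leaves the down-step undefined and is an
    error; sets are intersected with the measured genes first.
    """
    gene_names = list(gene_names)
    n_genes = len(gene_names)
    if n_genes < 2:
        raise ValueError("need >= 2 genes")
    X = np.asarray(sp.csr_matrix(expr).todense(), dtype=float)
    if X.shape[0] != n_genes:
        raise ValueError("expr rows must match gene_names")
    n_cells = X.shape[1]
    name_to_idx = {g: i for i, g in enumerate(gene_names)}

    member_idx: dict[str, np.ndarray] = {}
    for name, members in genesets.items():
        idx = np.array(sorted(name_to_idx[g] for g in set(members) if g in name_to_idx),
                       dtype=int)
        if idx.size == 0:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if idx.size == n_genes:
            raise ValueError(
                f"gene set {name!r} covers all genes; down-step undefined"
            )
        member_idx[name] = idx

    scores = np.zeros((len(member_idx), n_cells))
    member_mask = {
        name: np.isin(np.arange(n_genes), idx) for name, idx in member_idx.items()
    }
    for j in range(n_cells):
        order = np.argsort(-X[:, j], kind="stable")  # decreasing expression
        ranks = np.empty(n_genes)
        ranks[order] = np.arange(n_genes, 0, -1)  # top gene gets rank n
        for si, (name, mask) in enumerate(member_mask.items()):
            m = mask[order]
            w = ranks[order] ** tau
            up = np.where(m, w, 0.0)
            up_sum = up.sum()
            down = 1.0 / (n_genes - member_idx[name].size)
            steps = np.where(m, up / up_sum, -down)
            walk = np.cumsum(steps)
            scores[si, j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
    return pd.DataFrame(scores, index=pd.Index(list(member_mask), name="geneset"))


def compare_activity(
    scores: pd.DataFrame,
    groups,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    equal_var: bool = True,
    bh: bool = False,
) -> pd.DataFrame:
    """Two-sided t-test of per-set activity between two cell groups.

    ``groups`` is a per-cell label vector aligned with the score columns.
    Significance is judged at raw p < ``alpha`` by default (pathway
    comparisons are reported uncorrected); set ``bh=True`` to adjust across
    sets.  The t statistic is positive when ``group_a`` has higher activity.
    """
    groups = np.asarray(groups)
    if groups.size != scores.shape[1]:
        raise ValueError("groups length must match score columns")
    a_mask = groups == group_a
    b_mask = groups == group_b
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each group needs >= 2 cells")
    rows = []
    for name, vals in scores.iterrows():
        v = vals.to_numpy(dtype=float)
        res = student_t(v[a_mask], v[b_mask], equal_var=equal_var)
        rows.append(
            {
                "geneset": name,
                "t": res.statistic,
                "pvalue": res.pvalue,
                f"mean_{group_a}": res.mean_x,
                f"mean_{group_b}": res.mean_y,
            }
        )
    out = pd.DataFrame(rows).set_index("geneset")
    if bh:
        out["p_adj"] = bh_adjust(out["pvalue"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["pvalue"] < alpha
    return out
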