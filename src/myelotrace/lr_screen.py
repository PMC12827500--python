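"""Five-criteria ligand–receptor screen and differential-expression
annotation of surviving pairs.

A candidate ordered pair (A, B) of genes from the branch-gene subgroup map
is retained iff all five predicates hold:

1. A belongs to gene subgroup 1, 2, 3 or 6 (the microglia/aMG-elevated
   expression subgroups),
2. A is annotated "secreted",
3. B belongs to gene subgroup 4 or 5 (the monocyte/macrophage-elevated
   subgroups),
4. B is annotated "plasma membrane",
5. A and B interact (an undirected PPI edge exists).

The direction is fixed ligand -> receptor (CNS microglia to circulating
myeloid cells); self-pairs are excluded.  Candidates matching at least four
predicates are recorded with their predicate outcomes as an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .stats_core import star_label, student_t

__all__ = ["LRPair", "screen_lr_pairs", "lr_expression_stats",
           "eligibility_from_profiles"]

LIGAND_SUBGROUPS = frozenset({1, 2, 3, 6})
RECEPTOR_SUBGROUPS = frozenset({4, 5})


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    ligand_subgroup_ok: bool
    ligand_secreted: bool
    receptor_subgroup_ok: bool
    receptor_membrane: bool
    interaction_present: bool

    @property
    def retained(self) -> bool:
        return (
            self.ligand_subgroup_ok
            and self.ligand_secreted
            and self.receptor_subgroup_ok
            and self.receptor_membrane
            and self.interaction_present
        )

    @property
    def n_predicates(self) -> int:
        return sum(
            (
                self.ligand_subgroup_ok,
                self.ligand_secreted,
                self.receptor_subgroup_ok,
                self.receptor_membrane,
                self.interaction_present,
            )
        )


def eligibility_from_profiles(
    branch_result: pd.DataFrame,
    gene_subgroups,
    root_state: int,
) -> tuple[frozenset, frozenset]:
    """Derive ligand/receptor-eligible gene-subgroup ids from state profiles.

    A gene subgroup whose mean state profile (averaged over member genes)
    peaks at the trajectory's root state — the monocyte end — is
    receptor-eligible; subgroups peaking on the CNS branches are
    ligand-eligible.  This reproduces the screen's subgroup-eligibility
    logic when the clustering's arbitrary 1..k numbering does not match the
    canonical {1,2,3,6} / {4,5} split.
    """
    profile_cols = sorted(
        (c for c in branch_result.columns if c.startswith("mean_state_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    states = [int(c.rsplit("_", 1)[1]) for c in profile_cols]
    if root_state not in states:
        raise ValueError(f"root state {root_state} not among profiled states")
    gene_subgroups = pd.Series(gene_subgroups)
    ligand_ids, receptor_ids = set(), set()
    for sid in sorted(gene_subgroups.unique()):
        members = gene_subgroups.index[gene_subgroups == sid]
        prof = branch_result.loc[members, profile_cols].mean(axis=0)
        # z-score so abundant states do not dominate the peak
        z = (prof - prof.mean()) / (prof.std() or 1.0)
        peak_state = states[int(np.argmax(z.to_numpy()))]
        (receptor_ids if peak_state == root_state else ligand_ids).add(int(sid))
    return frozenset(ligand_ids), frozenset(receptor_ids)


def screen_lr_pairs(
    gene_subgroups: dict[str, int],
    locations: dict[str, str],
    ppi: set[frozenset],
    audit_min_predicates: int = 4,
    ligand_subgroups: frozenset = LIGAND_SUBGROUPS,
    receptor_subgroups: frozenset = RECEPTOR_SUBGROUPS,
) -> tuple[list[LRPair], list[LRPair]]:
    """Evaluate the five-predicate conjunction over all ordered gene pairs.

    Returns ``(retained, audit)``: the retained pairs (all five predicates
    true) and the audit trail of candidates matching at least
    ``audit_min_predicates`` predicates.  Both lists are sorted by
    (ligand, receptor) for determinism.  ``ligand_subgroups`` /
    ``receptor_subgroups`` default to the canonical numbering (1,2,3,6 for
    ligands; 4,5 for receptors).
    """
    if not gene_subgroups:
        raise ValueError("gene subgroup map is empty")
    if not ppi:
        raise ValueError("PPI edge set is empty")

    genes = sorted(gene_subgroups)
    retained: list[LRPair] = []
    audit: list[LRPair] = []
    for a in genes:
        for b in genes:
            if a == b:
                continue
            pair = LRPair(
                ligand=a,
                receptor=b,
                ligand_subgroup_ok=gene_subgroups[a] in ligand_subgroups,
                ligand_secreted=locations.get(a) == "secreted",
                receptor_subgroup_ok=gene_subgroups[b] in receptor_subgroups,
                receptor_membrane=locations.get(b) == "plasma membrane",
                interaction_present=frozenset((a, b)) in ppi,
            )
            if pair.retained:
                retained.append(pair)
            if pair.n_predicates >= audit_min_predicates:
                audit.append(pair)
    key = lambda p: (p.ligand, p.receptor)
    return sorted(retained, key=key), sorted(audit, key=key)


def lr_expression_stats(
    norm: sp.spmatrix | np.ndarray,
    gene_names,
    cell_meta: pd.DataFrame,
    genes: list[str],
    subgroups: list[str] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """TBI-vs-sham expression tests for screened genes per cell group.

    For each (gene, tissue, subgroup, timepoint) stratum with at least two
    cells per condition, a two-sided Student's t-test on log-normalized
    per-cell expression, with the significance star label attached.  The t
    statistic is positive when TBI expression is higher.
    """
    gene_names = list(gene_names)
    idx = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in genes if g not in idx]
    if missing:
        raise ValueError(f"genes not in matrix: {missing}")
    X = sp.csr_matrix(norm)
    if X.shape[1] != len(cell_meta):
        raise ValueError("matrix cells do not match metadata")

    rows = []
    strata = cell_meta.groupby(["tissue", "subgroup", "timepoint"], sort=True)
    for (tissue, sub, tp), meta in strata:
        if subgroups is not None and sub not in subgroups:
            continue
        pos = cell_meta.index.get_indexer(meta.index)
        cond = meta["condition"].to_numpy()
        tbi, sham = pos[cond == "TBI"], pos[cond == "Sham"]
        if tbi.size < 2 or sham.size < 2:
            continue
        for g in genes:
            expr = np.asarray(X[idx[g], :].todense()).ravel()
            res = student_t(expr[tbi], expr[sham], equal_var=equal_var)
            rows.append(
                {
                    "gene": g,
                    "tissue": tissue,
                    "subgroup": sub,
                    "timepoint": tp,
                    "t": res.statistic,
                    "pvalue": res.pvalue,
                    "mean_TBI": res.mean_x,
                    "mean_Sham": res.mean_y,
                    "n_TBI": res.n_x,
                    "n_Sham": res.n_y,
                    "star": star_label(res.pvalue),
                }
            )
    if not rows:
        raise ValueError("no stratum had >= 2 cells per condition")
    return pd.DataFrame(rows)
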