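"""Relative qPCR quantification by the 2^-ddCt method.

Technical replicates are averaged per biological replicate and gene; dCt is
the target Ct minus the reference-gene Ct within each biological replicate;
ddCt subtracts the control-group mean dCt; fold change is 2^-ddCt.  The
reported fold change is the mean across treated biological replicates with
its SD on the fold-change scale; the p-value comes from a Student's t-test
on dCt values (the log2 scale, where Ct noise is approximately additive),
BH-corrected across target genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats_core import bh_adjust, student_t

__all__ = ["ddct_analysis"]

REQUIRED_PLATE_COLUMNS = ("group", "bio_rep", "tech_rep", "gene", "ct")


def _validate_plate(plate: pd.DataFrame, reference_gene: str) -> None:
    missing = [c for c in REQUIRED_PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate missing columns: {missing}")
    if (plate["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    for (group, bio), wells in plate.groupby(["group", "bio_rep"]):
        if reference_gene not in set(wells["gene"]):
            raise ValueError(
                f"reference gene {reference_gene!r} missing for replicate "
                f"{group}/bio_rep={bio}"
            )


def ddct_analysis(
    plate: pd.DataFrame,
    reference_gene: str = "Gapdh",
    control_group: str = "control",
    log_scale_sd: bool = False,
) -> pd.DataFrame:
    """Fold changes, SDs and p-values per target gene from a Ct well table.

    ``plate`` has group / bio_rep / tech_rep / gene / ct columns.  Returns a
    DataFrame indexed by target gene with fold_change (2^-ddCt, treated vs
    control), sd (across treated biological replicates, fold-change scale by
    default, log2 scale if ``log_scale_sd``), pvalue (Student's t on dCt) and
    BH-adjusted p_adj.  Shifting all Ct values by a constant leaves results
    unchanged; swapping the group labels inverts the fold change.
    """
    _validate_plate(plate, reference_gene)
    groups = sorted(set(plate["group"]))
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in plate")
    treated_groups = [g for g in groups if g != control_group]
    if len(treated_groups) != 1:
        raise ValueError(f"expected exactly one treated group, got {treated_groups}")
    treated_group = treated_groups[0]

    # average technical replicates
    ct = (
        plate.groupby(["group", "bio_rep", "gene"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    ref = ct[ct["gene"] == reference_gene].set_index(["group", "bio_rep"])["ct"]
    targets = sorted(set(ct["gene"]) - {reference_gene})
    if not targets:
        raise ValueError("plate has no target genes")

    rows = []
    for gene in targets:
        sub = ct[ct["gene"] == gene]
        dct = (
            sub.set_index(["group", "bio_rep"])["ct"] - ref
        ).dropna()
        ctrl = dct.loc[control_group]
        trt = dct.loc[treated_group]
        if len(ctrl) < 2 or len(trt) < 2:
            raise ValueError(
                f"{gene}: need >= 2 biological replicates per group"
            )
        ddct = trt - ctrl.mean()
        fc = 2.0 ** (-ddct)
        res = student_t(trt.to_numpy(), ctrl.to_numpy())
        sd = float(np.std(np.log2(fc), ddof=1)) if log_scale_sd else float(fc.std(ddof=1))
        rows.append(
            {
                "gene": gene,
                "fold_change": float(fc.mean()),
                "sd": sd,
                "pvalue": res.pvalue,
                "n_bio_control": len(ctrl),
                "n_bio_treated": len(trt),
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["p_adj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
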