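"""Subgroup composition dynamics across tissue x condition x timepoint.

Percentages are pooled over mice within a grouping (matching atlas-level
reporting) and printed to two decimals with half-up rounding.  No inferential
statistics are attached: composition shifts are reported descriptively.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["round_percentage", "subgroup_proportions", "restricted_fractions",
           "condition_contrast"]


def round_percentage(count: int, total: int) -> float:
    """100 * count / total, half-up rounded to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be > 0")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _check_columns(cell_meta: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in cell_meta.columns]
    if missing:
        raise ValueError(f"grouping columns not in cell metadata: {missing}")


def subgroup_proportions(
    cell_meta: pd.DataFrame,
    by: list[str] | tuple[str, ...] = (),
    subgroups: list[str] | None = None,
) -> pd.DataFrame:
    """Cell counts and percentages per subgroup within each tissue x grouping.

    The denominator is all cells of the (tissue, grouping) stratum.  Within
    each stratum every subgroup of that tissue (or the supplied ``subgroups``
    list) is reported, zero-count subgroups as 0.00.  Percentages sum to 100
    up to rounding; counts sum to the denominator exactly.
    """
    by = list(by)
    _check_columns(cell_meta, ["tissue", "subgroup", *by])
    rows = []
    for tissue, tmeta in cell_meta.groupby("tissue", sort=True):
        subs = subgroups or sorted(tmeta["subgroup"].unique())
        groups = tmeta.groupby(by, sort=True) if by else [((), tmeta)]
        for key, gmeta in groups:
            if not isinstance(key, tuple):
                key = (key,)
            denom = len(gmeta)
            if denom == 0:
                raise ValueError(f"empty denominator group {tissue}/{key}")
            counts = gmeta["subgroup"].value_counts()
            for sub in subs:
                c = int(counts.get(sub, 0))
                rows.append(
                    {
                        "tissue": tissue,
                        **dict(zip(by, key)),
                        "subgroup": sub,
                        "count": c,
                        "denominator": denom,
                        "percentage": round_percentage(c, denom),
                    }
                )
    return pd.DataFrame(rows)


def restricted_fractions(
    cell_meta: pd.DataFrame,
    family: list[str],
    by: list[str] | tuple[str, ...] = ("condition", "timepoint"),
) -> pd.DataFrame:
    """Composition within a subgroup family (e.g. aMG / (MG + aMG)).

    The denominator is the number of family cells in each (tissue, grouping)
    stratum; family members absent from a stratum are reported as 0.00.
    Strata with no family cells at all are omitted.
    """
    if not family:
        raise ValueError("family must be a non-empty subgroup list")
    by = list(by)
    _check_columns(cell_meta, ["tissue", "subgroup", *by])
    fam_meta = cell_meta[cell_meta["subgroup"].isin(family)]
    if fam_meta.empty:
        raise ValueError(f"no cells belong to family {family}")
    return subgroup_proportions(fam_meta, by=by, subgroups=list(family))


def condition_contrast(table: pd.DataFrame) -> pd.DataFrame:
    """Signed percentage-point differences, TBI minus Sham, per subgroup and
    timepoint.

    ``table`` is the output of :func:`subgroup_proportions` or
    :func:`restricted_fractions` grouped by condition and timepoint.
    """
    needed = {"tissue", "condition", "timepoint", "subgroup", "percentage"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    wide = table.pivot_table(
        index=["tissue", "subgroup", "timepoint"],
        columns="condition",
        values="percentage",
        aggfunc="first",
    )
    for level in ("TBI", "Sham"):
        if level not in wide.columns:
            raise ValueError(f"condition level {level!r} missing from table")
    if wide["TBI"].isna().any() or wide["Sham"].isna().any():
        bad = wide.index[wide.isna().any(axis=1)][:3].tolist()
        raise ValueError(f"condition level missing for strata: {bad}")
    out = wide.reset_index()
    out["delta_pp"] = out["TBI"] - out["Sham"]
    return out[["tissue", "subgroup", "timepoint", "Sham", "TBI", "delta_pp"]]
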