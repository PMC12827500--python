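"""Ground-truth synthetic data emulating a multi-tissue TBI single-cell study.

Generates sparse count atlases (blood / cortex / hippocampus, with the
myeloid and non-myeloid subgroups of the study design), protein–protein
interaction tables, subcellular-location tables, GMT gene-set collections,
trajectory-structured data, and qPCR plates — all with known ground truth so
every downstream stage is testable offline.

Counts follow a negative binomial with a common dispersion; per-cell library
sizes are log-normal.  All randomness flows from a single integer seed via
``numpy.random.SeedSequence`` stream-splitting (PCG64), so a fixed seed gives
bit-identical output across runs and platforms.  Each public generator draws
from its own named child stream, so adding a call to one generator never
perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CellAtlas

__all__ = [
    "SimConfig",
    "SimTruth",
    "ConditionEffect",
    "BranchSpec",
    "default_config",
    "generate_atlas",
    "generate_ppi",
    "generate_locations",
    "generate_genesets",
    "generate_qpcr",
    "generate_trajectory_data",
    "generate_lr_fixture",
    "three_branch_spec",
]

CONDITIONS = ("Sham", "TBI")
TIMEPOINTS = ("24h", "7d")

# Stream ids for SeedSequence spawning; order is frozen (appending is fine,
# reordering would silently change output for a fixed seed).
_STREAMS = {
    "atlas": 0,
    "ppi": 1,
    "locations": 2,
    "genesets": 3,
    "qpcr": 4,
    "trajectory": 5,
    "lr_fixture": 6,
}


@dataclass(frozen=True)
class ConditionEffect:
    """A planted TBI-vs-sham log2 fold change for one gene in one cell group."""

    gene: str
    tissue: str
    subgroup: str
    timepoint: str
    log2_fc: float


@dataclass
class SimConfig:
    seed: int = 0
    tissues: tuple[str, ...] = ("blood", "cortex", "hippocampus")
    # per tissue: subgroup -> cells per condition x timepoint group
    subgroup_spec: dict[str, dict[str, int]] = field(default_factory=dict)
    n_genes: int = 300
    # subgroup -> [(gene, log2 elevation)]
    marker_spec: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    condition_effects: list[ConditionEffect] = field(default_factory=list)
    nb_dispersion: float = 0.3
    mito_gene_count: int = 10
    baseline_mean: float = 0.5
    libsize_sigma: float = 0.25
    # per tissue: number of mice per condition x timepoint group
    mice_per_group: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("n_genes, baseline_mean and nb_dispersion must be > 0")
        for tissue, groups in self.subgroup_spec.items():
            if tissue not in self.tissues:
                raise ValueError(f"subgroup_spec references unknown tissue {tissue!r}")
            for sub, n in groups.items():
                if n <= 0:
                    raise ValueError(f"cell count for {tissue}/{sub} must be > 0")
        universe = set(self.gene_universe())
        for sub, markers in self.marker_spec.items():
            if not any(sub in groups for groups in self.subgroup_spec.values()):
                raise ValueError(f"marker_spec references unknown subgroup {sub!r}")
            for gene, _ in markers:
                if gene not in universe:
                    raise ValueError(f"marker gene {gene!r} not in gene universe")
        for eff in self.condition_effects:
            if eff.gene not in universe:
                raise ValueError(f"effect gene {eff.gene!r} not in gene universe")
            if eff.tissue not in self.tissues:
                raise ValueError(f"effect tissue {eff.tissue!r} unknown")
            if eff.subgroup not in self.subgroup_spec.get(eff.tissue, {}):
                raise ValueError(
                    f"effect subgroup {eff.subgroup!r} unknown in {eff.tissue!r}"
                )
            if eff.timepoint not in TIMEPOINTS:
                raise ValueError(f"effect timepoint {eff.timepoint!r} unknown")

    def gene_universe(self) -> list[str]:
        """Deterministic gene-name list: named genes, mito genes, filler."""
        named: list[str] = []
        for markers in self.marker_spec.values():
            named.extend(g for g, _ in markers)
        named.extend(e.gene for e in self.condition_effects)
        named = sorted(set(named))
        mito = [f"mt-Sim{i + 1}" for i in range(self.mito_gene_count)]
        n_fill = self.n_genes - len(named) - len(mito)
        if n_fill < 0:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {len(named)} named + "
                f"{len(mito)} mito genes"
            )
        filler = [f"Gene{i + 1:04d}" for i in range(n_fill)]
        return named + mito + filler

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[_STREAMS[stream]]
        )


@dataclass
class SimTruth:
    """Ground truth for a generated dataset."""

    cell_labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    de_effects: list[ConditionEffect] = field(default_factory=list)
    gene_programs: dict[str, int] = field(default_factory=dict)
    lr_pairs: list[tuple[str, str]] = field(default_factory=list)
    qpcr_fold_changes: dict[str, float] = field(default_factory=dict)


# The study's subgroup inventory with the atlas-level cell totals it reports;
# the default configuration scales these down uniformly.  CD8T and cortex aMG
# totals are the remainders that complete the 22,800 / 27,081 atlas totals
# (they reproduce the reported 6.86% / 8.05%).
BLOOD_SUBGROUPS = {
    "B.cells": 13416, "CD4T": 3690, "CD8T": 1565, "NK.cells": 1216,
    "Ly6c+.Mon": 1015, "GRAN": 857, "Treml4+.Mon": 816, "MEGK": 225,
}
CORTEX_SUBGROUPS = {
    "NEU": 6392, "ASC": 4516, "ODC": 4023, "END": 3907, "aMG": 2180,
    "MG": 1764, "OPC": 1480, "NeuroG1": 1167, "PER": 525, "nODC": 295,
    "MAC": 283, "SMC": 275, "NeuroG2": 274,
}
HIPPOCAMPUS_SUBGROUPS = {
    "ODC": 5808, "ASC": 4598, "NEU": 4270, "END": 3914, "aMG": 2641,
    "OPC": 2018, "MG": 1801, "CPE": 910, "nODC": 531, "MAC": 513,
    "PER": 441, "SMC": 416, "CR": 366, "NeuroG1": 277, "FB": 221,
    "NeuroG2": 158, "EPEN": 129,
}


def study_cell_meta() -> pd.DataFrame:
    """Per-cell metadata reconstructing the study's atlas-level composition.

    One row per cell with tissue and subgroup drawn from the reported totals
    (22,800 blood / 27,081 cortex / 29,012 hippocampus cells); condition and
    timepoint are not part of the atlas-level tallies and are filled with a
    placeholder.  Intended for recomputing the atlas composition table.
    """
    rows = []
    for tissue, subs in (
        ("blood", BLOOD_SUBGROUPS),
        ("cortex", CORTEX_SUBGROUPS),
        ("hippocampus", HIPPOCAMPUS_SUBGROUPS),
    ):
        for sub, n in subs.items():
            rows.append(
                pd.DataFrame(
                    {
                        "tissue": tissue,
                        "subgroup": sub,
                        "condition": "TBI",
                        "timepoint": "24h",
                    },
                    index=range(n),
                )
            )
    return pd.concat(rows, ignore_index=True)


def default_config(
    seed: int = 0,
    scale: float = 0.25,
    amg_expansion_factor: float = 2.0,
    min_cells_per_group: int = 20,
) -> SimConfig:
    """Study-emulating default configuration.

    Three tissues with the study's subgroup inventories; each subgroup's
    cells per condition x timepoint group derive from the atlas-level totals
    the study reports, split evenly over the four condition x timepoint
    groups and scaled by ``scale`` (a uniform down-scaling for tractable
    simulation, floored at ``min_cells_per_group``).  The aMG subgroup is
    expanded by ``amg_expansion_factor`` in the TBI-24h CNS groups — the
    rapid microglial-activation signal — via a per-group override.
    Condition effects plant the study's reported regulation:
    Ccl2/Ccl7/Tnf up at 24 h in CNS microglia, Grn up at 7 d, and
    Ccr2/Tnfrsf1b up at 24 h and Flna at 7 d in blood monocytes.
    """
    spec: dict[str, dict[str, int]] = {}
    for tissue, subs in (
        ("blood", BLOOD_SUBGROUPS),
        ("cortex", CORTEX_SUBGROUPS),
        ("hippocampus", HIPPOCAMPUS_SUBGROUPS),
    ):
        spec[tissue] = {
            s: max(min_cells_per_group, round(total * scale / 4))
            for s, total in subs.items()
        }

    markers: dict[str, list[tuple[str, float]]] = {
        "Ly6c+.Mon": [("Ly6c2", 3.0), ("Ccr2", 1.5), ("Flna", 1.0)],
        "Treml4+.Mon": [("Treml4", 3.0), ("Tnfrsf1b", 1.0), ("Flna", 1.0)],
        "MG": [("P2ry12", 3.0), ("Tmem119", 3.0)],
        "aMG": [("P2ry12", 2.0), ("Ccl2", 1.0), ("Ccl7", 1.0), ("Tnf", 1.0)],
        "MAC": [("Ms4a7", 3.0), ("Mrc1", 2.5)],
        "B.cells": [("Cd79a", 3.0)],
        "NEU": [("Snap25", 3.0)],
        "ASC": [("Aqp4", 3.0)],
    }

    effects: list[ConditionEffect] = []
    for tissue in ("cortex", "hippocampus"):
        for sub in (("aMG",) if tissue == "cortex" else ("MG", "aMG")):
            effects += [
                ConditionEffect("Ccl2", tissue, sub, "24h", 1.5),
                ConditionEffect("Ccl7", tissue, sub, "24h", 1.5),
                ConditionEffect("Tnf", tissue, sub, "24h", 1.5),
            ]
        for sub in ("MG", "aMG"):
            effects.append(ConditionEffect("Grn", tissue, sub, "7d", 1.2))
    effects += [
        ConditionEffect("Ccr2", "blood", "Ly6c+.Mon", "24h", 1.2),
        ConditionEffect("Tnfrsf1b", "blood", "Ly6c+.Mon", "24h", 1.2),
        ConditionEffect("Tnfrsf1b", "blood", "Treml4+.Mon", "24h", 1.2),
        ConditionEffect("Flna", "blood", "Ly6c+.Mon", "7d", 1.0),
        ConditionEffect("Flna", "blood", "Treml4+.Mon", "7d", 1.0),
    ]

    cfg = SimConfig(
        seed=seed,
        n_genes=1000,
        subgroup_spec=spec,
        marker_spec=markers,
        condition_effects=effects,
        mice_per_group={"blood": 3, "cortex": 3, "hippocampus": 3},
    )
    # composition ground truth: aMG expands in TBI-24h CNS tissue
    cfg.group_overrides = {  # type: ignore[attr-defined]
        (t, "aMG", "TBI", "24h"): round(spec[t]["aMG"] * amg_expansion_factor)
        for t in ("cortex", "hippocampus")
    }
    return cfg


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, disp: float) -> np.ndarray:
    """NB(mean=mu, var=mu + disp*mu^2) via the gamma–Poisson mixture."""
    shape = 1.0 / disp
    lam = rng.gamma(shape, mu * disp)
    return rng.poisson(lam)


def generate_atlas(config: SimConfig) -> tuple[CellAtlas, SimTruth]:
    """Generate a multi-tissue count atlas with planted markers and effects.

    Negative-binomial counts; marker genes elevated 2**lfc in their subgroup;
    condition effects applied multiplicatively to TBI cells at the stated
    timepoint; mitochondrial genes carry the mouse ``mt-`` prefix and a
    modestly elevated baseline so mito fractions are realistic (a few percent
    of counts).
    """
    genes = config.gene_universe()
    gene_idx = {g: i for i, g in enumerate(genes)}
    rng = config.rng("atlas")

    base = np.full(len(genes), config.baseline_mean)
    mito_mask = np.array([g.startswith("mt-") for g in genes])
    base[mito_mask] *= 4.0  # mito transcripts are abundant

    overrides: dict = getattr(config, "group_overrides", {}) or {}

    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for tissue in config.tissues:
        n_mice = config.mice_per_group.get(tissue, 3)
        for cond in CONDITIONS:
            for tp in TIMEPOINTS:
                mice = [f"{tissue}_{cond}_{tp}_m{j + 1}" for j in range(n_mice)]
                for sub, n_default in config.subgroup_spec.get(tissue, {}).items():
                    n = overrides.get((tissue, sub, cond, tp), n_default)
                    mu_gene = base.copy()
                    for gene, lfc in config.marker_spec.get(sub, []):
                        mu_gene[gene_idx[gene]] *= 2.0**lfc
                    if cond == "TBI":
                        for eff in config.condition_effects:
                            if (
                                eff.tissue == tissue
                                and eff.subgroup == sub
                                and eff.timepoint == tp
                            ):
                                mu_gene[gene_idx[eff.gene]] *= 2.0**eff.log2_fc
                    libs = rng.lognormal(0.0, config.libsize_sigma, size=n)
                    mu = mu_gene[:, None] * libs[None, :]
                    blocks.append(_nb_sample(rng, mu, config.nb_dispersion))
                    for j in range(n):
                        meta_rows.append(
                            {
                                "tissue": tissue,
                                "subgroup": sub,
                                "condition": cond,
                                "timepoint": tp,
                                "mouse": mice[j % n_mice],
                            }
                        )

    counts = sp.csr_matrix(np.concatenate(blocks, axis=1))
    cell_meta = pd.DataFrame(meta_rows)
    cell_meta.index = pd.Index(
        [f"{r['tissue'][:2].upper()}-{i:06d}" for i, r in enumerate(meta_rows)],
        name="barcode",
    )
    gene_meta = pd.DataFrame(index=pd.Index(genes, name="symbol"))
    gene_meta["mito"] = mito_mask
    atlas = CellAtlas(counts=counts, gene_meta=gene_meta, cell_meta=cell_meta)
    truth = SimTruth(
        cell_labels=cell_meta[["tissue", "subgroup"]].copy(),
        de_effects=list(config.condition_effects),
    )
    return atlas, truth


def generate_ppi(
    config: SimConfig,
    true_pairs: list[tuple[str, str]],
    n_decoys: int,
    subgroups: dict[str, int] | None = None,
    locations: dict[str, str] | None = None,
) -> set[frozenset]:
    """Undirected, deduplicated interaction table: true pairs plus decoys.

    When ``subgroups``/``locations`` context is supplied, decoy edges attach
    a non-eligible gene (one absent from the subgroup map) to an eligible
    partner, so each decoy fails the screen on its broken side.  Without
    context, decoys are random edges among filler genes, which fail the
    screen by lacking annotations either way.  For decoys failing *exactly*
    one named criterion, see :func:`generate_lr_fixture`, which also
    fabricates the annotations the failure modes need.
    """
    universe = config.gene_universe()
    uni_set = set(universe)
    for a, b in true_pairs:
        if a not in uni_set or b not in uni_set:
            raise ValueError(f"pair ({a}, {b}) not in gene universe")
        if a == b:
            raise ValueError(f"self-pair ({a}, {a}) not allowed")
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = config.rng("ppi")
    edges: set[frozenset] = {frozenset(p) for p in true_pairs}
    target = len(edges) + n_decoys

    if subgroups is not None:
        eligible = sorted(subgroups)
        filler = sorted(uni_set - set(subgroups))
    else:
        eligible = []
        filler = [g for g in universe if g.startswith("Gene")] or universe
    attempts = 0
    while len(edges) < target:
        attempts += 1
        if attempts > 1000 * (n_decoys + 1):
            raise ValueError("cannot construct enough distinct decoy edges")
        bad = filler[int(rng.integers(len(filler)))]
        if eligible:
            other = eligible[int(rng.integers(len(eligible)))]
        else:
            other = filler[int(rng.integers(len(filler)))]
        edge = frozenset((bad, other))
        if len(edge) == 2 and edge not in edges:
            edges.add(edge)
    return edges


def generate_locations(
    config: SimConfig,
    secreted: list[str],
    membrane: list[str],
) -> dict[str, str]:
    """Assign every gene exactly one subcellular-location label.

    Listed genes get their listed label; everything else is 'other'.
    """
    overlap = set(secreted) & set(membrane)
    if overlap:
        raise ValueError(f"genes in both secreted and membrane lists: {sorted(overlap)}")
    universe = config.gene_universe()
    uni = set(universe)
    for g in list(secreted) + list(membrane):
        if g not in uni:
            raise ValueError(f"gene {g!r} not in gene universe")
    out = {g: "other" for g in universe}
    out.update({g: "secreted" for g in secreted})
    out.update({g: "plasma membrane" for g in membrane})
    return out


def generate_genesets(
    config: SimConfig,
    planted: list[tuple[str, list[str]]],
    n_filler: int = 20,
    filler_size: int = 15,
) -> dict[str, list[str]]:
    """GMT-style collection: planted sets verbatim plus uniform filler sets."""
    universe = config.gene_universe()
    uni = set(universe)
    rng = config.rng("genesets")
    out: dict[str, list[str]] = {}
    for name, members in planted:
        bad = [g for g in members if g not in uni]
        if bad:
            raise ValueError(f"planted set {name!r} has genes outside universe: {bad}")
        if not members:
            raise ValueError(f"planted set {name!r} is empty")
        out[name] = list(members)
    for i in range(n_filler):
        members = rng.choice(universe, size=min(filler_size, len(universe)), replace=False)
        out[f"FILLER_{i + 1:03d}"] = sorted(members.tolist())
    return out


def generate_qpcr(
    config: SimConfig,
    genes: list[str],
    fold_changes: list[float],
    n_bio: int = 3,
    n_tech: int = 3,
    ct_sd: float = 0.2,
    reference_gene: str = "Gapdh",
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a qPCR plate with known fold changes.

    The reference gene's Ct is constant in expectation across groups; each
    target's treated-group ΔCt is shifted by -log2(FC).  Gaussian Ct noise
    with sd ``ct_sd`` is added per well.  Wells carry sample id, group,
    biological/technical replicate ids, gene and Ct, matching the plate
    reader export the analysis module consumes.
    """
    if len(genes) != len(fold_changes):
        raise ValueError("fold_changes must align with genes")
    if any(fc <= 0 for fc in fold_changes):
        raise ValueError("fold changes must be positive")
    rng = config.rng("qpcr")
    ref_ct = 18.0
    base_target_ct = 24.0
    rows = []
    for group in ("control", "treated"):
        for b in range(1, n_bio + 1):
            sample = f"{group}_b{b}"
            for t in range(1, n_tech + 1):
                noise = rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0
                rows.append(
                    {
                        "sample": sample, "group": group, "bio_rep": b,
                        "tech_rep": t, "gene": reference_gene,
                        "ct": ref_ct + noise,
                    }
                )
            for gene, fc in zip(genes, fold_changes):
                shift = -math.log2(fc) if group == "treated" else 0.0
                for t in range(1, n_tech + 1):
                    noise = rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample": sample, "group": group, "bio_rep": b,
                            "tech_rep": t, "gene": gene,
                            "ct": base_target_ct + shift + noise,
                        }
                    )
    plate = pd.DataFrame(rows)
    truth = SimTruth(qpcr_fold_changes=dict(zip(genes, fold_changes)))
    return plate, truth


@dataclass(frozen=True)
class BranchSpec:
    """One branch of a rooted trajectory tree.

    ``parent`` names the branch this one forks from (None for the root
    branch).  ``program`` maps genes to log2 elevations applied to cells on
    this branch; ``subgroup`` is the cell-type label given to its cells.
    """

    name: str
    parent: str | None
    length: float
    n_cells: int
    program: dict[str, float] = field(default_factory=dict)
    subgroup: str = "cell"


def three_branch_spec(
    n_cells: int = 300,
    genes_per_program: int = 10,
    lfc: float = 2.0,
) -> list[BranchSpec]:
    """The study-like three-state topology: a monocyte root branch forking
    into a microglia branch and an activated-microglia branch.

    Six gene programs are planted — for each branch, one program elevated on
    that branch only and one elevated on the other two branches — giving six
    distinct standardized state profiles for branch-gene clustering to
    recover.
    """
    branches = ["Mon", "MG", "aMG"]
    programs: dict[str, dict[str, float]] = {b: {} for b in branches}
    gi = 0
    for k, b in enumerate(branches):
        solo = [f"Prog{gi + j + 1:03d}" for j in range(genes_per_program)]
        gi += genes_per_program
        duo = [f"Prog{gi + j + 1:03d}" for j in range(genes_per_program)]
        gi += genes_per_program
        for g in solo:
            programs[b][g] = lfc
        for other in branches:
            if other != b:
                for g in duo:
                    programs[other][g] = lfc
    return [
        BranchSpec("Mon", None, 10.0, n_cells, programs["Mon"], "Ly6c+.Mon"),
        BranchSpec("MG", "Mon", 10.0, n_cells, programs["MG"], "MG"),
        BranchSpec("aMG", "Mon", 10.0, n_cells, programs["aMG"], "aMG"),
    ]


def generate_trajectory_data(
    config: SimConfig,
    branch_spec: list[BranchSpec],
    noise_sd: float = 0.6,
) -> tuple[CellAtlas, SimTruth]:
    """Place cells along a rooted branch tree in 2-D latent space with
    branch-specific gene programs.

    Cells are uniform along each branch with isotropic Gaussian positional
    noise; counts are negative binomial with the branch program's genes
    elevated.  The returned truth records each cell's branch, its true
    ordering (distance from the tree root), and the gene -> program map.
    The latent coordinates are stored in ``cell_labels[['x', 'y']]`` so
    trajectory fitting can be exercised directly on them.
    """
    by_name = {b.name: b for b in branch_spec}
    roots = [b for b in branch_spec if b.parent is None]
    if len(roots) != 1:
        raise ValueError("branch_spec must have exactly one root branch")
    for b in branch_spec:
        if b.parent is not None and b.parent not in by_name:
            raise ValueError(f"branch {b.name!r} has unknown parent {b.parent!r}")
        if b.n_cells <= 0 or b.length <= 0:
            raise ValueError("branch n_cells and length must be > 0")

    # geometry: root along +x; each child rotated +/-70 degrees from parent
    geom: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}  # start, unit, depth

    def _place(b: BranchSpec, start, direction, depth) -> None:
        geom[b.name] = (np.asarray(start, float), np.asarray(direction, float), depth)
        children = [c for c in branch_spec if c.parent == b.name]
        end = np.asarray(start) + b.length * np.asarray(direction)
        angles = np.linspace(-70, 70, num=max(len(children), 1))
        base_angle = math.atan2(direction[1], direction[0])
        for ang, c in zip(angles, children):
            theta = base_angle + math.radians(ang)
            _place(c, end, np.array([math.cos(theta), math.sin(theta)]), depth + b.length)

    _place(roots[0], np.zeros(2), np.array([1.0, 0.0]), 0.0)

    genes = config.gene_universe()
    # program genes outside the configured universe are appended to it
    extra = sorted(
        {g for b in branch_spec for g in b.program} - set(genes)
    )
    genes = genes + extra
    gene_idx = {g: i for i, g in enumerate(genes)}

    rng = config.rng("trajectory")
    base = np.full(len(genes), config.baseline_mean)
    mito_mask = np.array([g.startswith("mt-") for g in genes])
    base[mito_mask] *= 4.0

    blocks, meta_rows, xs, ys, orders, branch_labels = [], [], [], [], [], []
    for b in branch_spec:
        start, direction, depth = geom[b.name]
        t = np.sort(rng.uniform(0.0, b.length, size=b.n_cells))
        pos = start[None, :] + t[:, None] * direction[None, :]
        pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)
        mu_gene = base.copy()
        for g, lfc in b.program.items():
            mu_gene[gene_idx[g]] *= 2.0**lfc
        libs = rng.lognormal(0.0, config.libsize_sigma, size=b.n_cells)
        mu = mu_gene[:, None] * libs[None, :]
        blocks.append(_nb_sample(rng, mu, config.nb_dispersion))
        xs.extend(pos[:, 0]); ys.extend(pos[:, 1])
        orders.extend(depth + t)
        branch_labels.extend([b.name] * b.n_cells)
        meta_rows.extend(
            {
                "tissue": "mixed", "subgroup": b.subgroup,
                "condition": "TBI", "timepoint": "24h", "mouse": "sim_m1",
            }
            for _ in range(b.n_cells)
        )

    counts = sp.csr_matrix(np.concatenate(blocks, axis=1))
    cell_meta = pd.DataFrame(meta_rows)
    cell_meta.index = pd.Index(
        [f"TR-{i:06d}" for i in range(len(meta_rows))], name="barcode"
    )
    gene_meta = pd.DataFrame(index=pd.Index(genes, name="symbol"))
    gene_meta["mito"] = mito_mask
    atlas = CellAtlas(counts=counts, gene_meta=gene_meta, cell_meta=cell_meta)

    labels = cell_meta[["tissue", "subgroup"]].copy()
    labels["branch"] = branch_labels
    labels["x"] = xs
    labels["y"] = ys
    labels["true_order"] = orders
    gene_programs: dict[str, int] = {}
    # a program id per distinct elevation pattern across branches
    pattern_ids: dict[tuple, int] = {}
    all_prog_genes = sorted({g for b in branch_spec for g in b.program})
    for g in all_prog_genes:
        pattern = tuple(round(b.program.get(g, 0.0), 6) for b in branch_spec)
        pid = pattern_ids.setdefault(pattern, len(pattern_ids) + 1)
        gene_programs[g] = pid
    truth = SimTruth(cell_labels=labels, gene_programs=gene_programs)
    return atlas, truth


def generate_lr_fixture(
    config: SimConfig | None = None,
    n_decoys: int = 50,
) -> tuple[dict[str, int], dict[str, str], set[frozenset], SimTruth]:
    """The study's ligand–receptor configuration as a ready-made fixture.

    Ccl2, Ccl7, Tnf and Grn sit in ligand-eligible gene subgroups (1–3, 6)
    and are secreted; Ccr2, Tnfrsf1b and Flna sit in receptor-eligible
    subgroups (4–5) and are plasma membrane; the four true interaction edges
    are present plus ``n_decoys`` decoy edges, each constructed (with a
    dedicated annotated decoy gene) to fail exactly one of the four
    annotation criteria — wrong ligand subgroup, ligand not secreted, wrong
    receptor subgroup, receptor not plasma membrane — cycling through the
    four failure modes so screen tests localize failures.
    Returns (gene_subgroups, locations, ppi, truth).
    """
    if config is None:
        config = default_config()
    true_pairs = [
        ("Ccl2", "Ccr2"),
        ("Ccl7", "Ccr2"),
        ("Tnf", "Tnfrsf1b"),
        ("Grn", "Flna"),
    ]
    ligands = ["Ccl2", "Ccl7", "Tnf", "Grn"]
    receptors = ["Ccr2", "Tnfrsf1b", "Flna"]
    subgroups = {
        "Ccl2": 1, "Ccl7": 2, "Tnf": 6, "Grn": 3,
        "Ccr2": 4, "Tnfrsf1b": 5, "Flna": 4,
    }
    locations = generate_locations(
        config,
        secreted=ligands,
        membrane=receptors,
    )
    rng = config.rng("lr_fixture")
    ppi: set[frozenset] = {frozenset(p) for p in true_pairs}
    for i in range(n_decoys):
        d = f"Decoy{i + 1:03d}"
        mode = i % 4
        if mode == 0:  # fails only criterion 1: ligand-side gene in subgroup 4/5
            subgroups[d] = int(rng.choice([4, 5]))
            locations[d] = "secreted"
            ppi.add(frozenset((d, receptors[int(rng.integers(len(receptors)))])))
        elif mode == 1:  # fails only criterion 2: eligible subgroup, not secreted
            subgroups[d] = int(rng.choice([1, 2, 3, 6]))
            locations[d] = "other"
            ppi.add(frozenset((d, receptors[int(rng.integers(len(receptors)))])))
        elif mode == 2:  # fails only criterion 3: receptor-side gene in 1/2/3/6
            subgroups[d] = int(rng.choice([1, 2, 3, 6]))
            locations[d] = "plasma membrane"
            ppi.add(frozenset((ligands[int(rng.integers(len(ligands)))], d)))
        else:  # fails only criterion 4: subgroup 4/5 but not plasma membrane
            subgroups[d] = int(rng.choice([4, 5]))
            locations[d] = "other"
            ppi.add(frozenset((ligands[int(rng.integers(len(ligands)))], d)))
    truth = SimTruth(lr_pairs=true_pairs)
    return subgroups, locations, ppi, truth
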