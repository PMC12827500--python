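"""On-disk formats: 10x-style Matrix Market triplets, TSV metadata, GMT
gene sets, PPI edge lists, and subcellular-location tables.

All parsers validate strictly and raise :class:`ParseError` rather than
silently coercing malformed rows.  Matrix Market files use 1-based indices on
disk (the standard dialect); in memory everything is 0-based.  ``.gz``
compression is handled transparently by file suffix.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

VALID_CONDITIONS = frozenset({"TBI", "Sham"})
VALID_TIMEPOINTS = frozenset({"24h", "7d"})
REQUIRED_CELL_COLUMNS = ("tissue", "subgroup", "condition", "timepoint", "mouse")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CellAtlas:
    """Sparse gene x cell count matrix with per-gene and per-cell metadata.

    ``counts`` is genes x cells (the 10x on-disk orientation), non-negative
    integers.  ``gene_meta`` is indexed by gene symbol with a boolean ``mito``
    column; ``cell_meta`` is indexed by barcode with tissue / subgroup /
    condition / timepoint / mouse columns once metadata is attached.
    """

    counts: sp.csr_matrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.gene_meta):
            raise ParseError(
                f"matrix has {self.counts.shape[0]} genes but gene_meta has "
                f"{len(self.gene_meta)} rows"
            )
        if len(self.cell_meta) and self.counts.shape[1] != len(self.cell_meta):
            raise ParseError(
                f"matrix has {self.counts.shape[1]} cells but cell_meta has "
                f"{len(self.cell_meta)} rows"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ParseError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ParseError("counts must be integral")
        if len(self.cell_meta) and self.cell_meta.index.has_duplicates:
            dups = self.cell_meta.index[self.cell_meta.index.duplicated()][:3]
            raise ParseError(f"duplicate barcodes: {list(dups)} ...")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_names(self) -> np.ndarray:
        return self.gene_meta.index.to_numpy()

    @property
    def barcodes(self) -> np.ndarray:
        return self.cell_meta.index.to_numpy()

    def subset_cells(self, mask) -> "CellAtlas":
        mask = np.asarray(mask)
        return CellAtlas(
            counts=sp.csr_matrix(self.counts[:, mask]),
            gene_meta=self.gene_meta,
            cell_meta=self.cell_meta.iloc[mask]
            if len(self.cell_meta)
            else self.cell_meta,
        )


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise ParseError(f"missing {stem}[.gz] in {dirpath}")


def _dedupe_symbols(symbols: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            new = f"{s}.{seen[s]}"
            logger.warning("duplicate gene symbol %r renamed to %r", s, new)
            out.append(new)
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_10x_triplet(dirpath, mito_prefix: str = "mt-") -> CellAtlas:
    """Read a 10x-style triplet directory (matrix.mtx + features + barcodes).

    Features may have one column (symbol) or three (id, symbol, type); the
    symbol is the gene key either way.  Duplicate symbols are disambiguated
    with a numeric suffix and logged.
    """
    dirpath = Path(dirpath)
    mtx_path = _find(dirpath, "matrix.mtx")
    try:
        feat_path = _find(dirpath, "features.tsv")
    except ParseError:
        feat_path = _find(dirpath, "genes.tsv")
    bc_path = _find(dirpath, "barcodes.tsv")

    try:
        with _open_maybe_gz(mtx_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # mmread raises assorted ValueErrors
        raise ParseError(f"{mtx_path}: malformed Matrix Market file: {exc}") from exc
    mat = sp.csr_matrix(mat)

    with _open_maybe_gz(feat_path) as fh:
        feat = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    if feat.shape[1] == 1:
        symbols = feat[0].tolist()
    elif feat.shape[1] >= 2:
        symbols = feat[1].tolist()
    else:
        raise ParseError(f"{feat_path}: expected 1 or 3 columns")
    symbols = _dedupe_symbols(symbols)

    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if len(set(barcodes)) != len(barcodes):
        raise ParseError(f"{bc_path}: duplicate barcodes")

    if mat.shape != (len(symbols), len(barcodes)):
        raise ParseError(
            f"{mtx_path}: matrix is {mat.shape} but features/barcodes declare "
            f"({len(symbols)}, {len(barcodes)})"
        )
    gene_meta = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    gene_meta["mito"] = gene_meta.index.str.lower().str.startswith(
        mito_prefix.lower()
    )
    cell_meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return CellAtlas(counts=mat, gene_meta=gene_meta, cell_meta=cell_meta)


def write_10x_triplet(dirpath, atlas: CellAtlas) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv (+ metadata.tsv if present)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    coo = atlas.counts.tocoo().astype(np.int64)
    scipy.io.mmwrite(str(dirpath / "matrix.mtx"), coo, field="integer")
    pd.Series(atlas.gene_names).to_csv(
        dirpath / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(atlas.barcodes).to_csv(
        dirpath / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if atlas.cell_meta.shape[1]:
        atlas.cell_meta.to_csv(dirpath / "metadata.tsv", sep="\t")


def read_metadata(path, atlas: CellAtlas) -> CellAtlas:
    """Attach a per-cell metadata TSV (barcode-keyed) to an atlas.

    Inner join on barcode: cells without metadata are dropped and the count
    logged.  Requires the tissue/subgroup/condition/timepoint/mouse columns
    and validates the condition and timepoint vocabularies.
    """
    with _open_maybe_gz(Path(path)) as fh:
        meta = pd.read_csv(fh, sep="\t", dtype=str)
    if "barcode" not in meta.columns:
        raise ParseError(f"{path}: missing required 'barcode' column")
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {missing}")
    bad_cond = set(meta["condition"]) - VALID_CONDITIONS
    if bad_cond:
        raise ParseError(
            f"{path}: condition values {sorted(bad_cond)} not in "
            f"{sorted(VALID_CONDITIONS)}"
        )
    bad_tp = set(meta["timepoint"]) - VALID_TIMEPOINTS
    if bad_tp:
        raise ParseError(
            f"{path}: timepoint values {sorted(bad_tp)} not in "
            f"{sorted(VALID_TIMEPOINTS)}"
        )
    meta = meta.set_index("barcode")
    if meta.index.has_duplicates:
        raise ParseError(f"{path}: duplicate barcodes in metadata")

    keep = np.isin(atlas.barcodes, meta.index.to_numpy())
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d cells without metadata", n_dropped)
    sub = atlas.subset_cells(keep)
    cell_meta = meta.loc[sub.barcodes, list(REQUIRED_CELL_COLUMNS)]
    return CellAtlas(counts=sub.counts, gene_meta=sub.gene_meta, cell_meta=cell_meta)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with _open_maybe_gz(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member, got {len(parts)} fields"
                )
            name, members = parts[0], [g for g in parts[2:] if g]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(path, genesets: dict[str, list[str]], descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in genesets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_ppi(path) -> set[frozenset]:
    """Read a protein–protein interaction TSV into an undirected edge set.

    Expects ``gene_a``/``gene_b`` columns.  (A,B) and (B,A) collapse to one
    edge; self-loops are rejected.
    """
    with _open_maybe_gz(Path(path)) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    edges: set[frozenset] = set()
    for a, b in zip(df["gene_a"], df["gene_b"]):
        if a == b:
            raise ParseError(f"{path}: self-interaction {a!r} not allowed")
        edges.add(frozenset((a, b)))
    return edges


def write_ppi(path, edges) -> None:
    rows = sorted(tuple(sorted(e)) for e in edges)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_locations(path) -> dict[str, str]:
    """Read a gene -> subcellular-location TSV (columns ``gene``, ``location``).

    Labels are 'secreted', 'plasma membrane' or 'other'.  A gene listed twice
    with conflicting labels is an error.
    """
    with _open_maybe_gz(Path(path)) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("gene", "location"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    valid = {"secreted", "plasma membrane", "other"}
    out: dict[str, str] = {}
    for gene, loc in zip(df["gene"], df["location"]):
        if loc not in valid:
            raise ParseError(f"{path}: invalid location {loc!r} for {gene!r}")
        if gene in out and out[gene] != loc:
            raise ParseError(
                f"{path}: conflicting locations for {gene!r}: "
                f"{out[gene]!r} vs {loc!r}"
            )
        out[gene] = loc
    return out


def write_locations(path, locations: dict[str, str]) -> None:
    pd.DataFrame(
        sorted(locations.items()), columns=["gene", "location"]
    ).to_csv(path, sep="\t", index=False)
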