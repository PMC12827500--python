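"""Per-tissue preprocessing: cell QC, depth normalization, variable-gene
selection and PCA embedding.

The QC rule excludes cells with fewer than 200 or more than 6,000 detected
genes, or more than 10% mitochondrial counts; the exclusion inequalities are
strict, so boundary cells are retained.  Normalization is the LogNormalize
convention: ln(1 + count / cell_total * 1e4).  Variable genes are ranked by
vst-style standardized variance (mean–variance trend on log10 scale,
standardized counts clipped at sqrt(N)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import CellAtlas

logger = logging.getLogger(__name__)


@dataclass
class CellQC:
    """Per-cell QC statistics as a DataFrame wrapper."""

    table: pd.DataFrame  # columns: detected_genes, mito_fraction, total_counts


def compute_cell_qc(atlas: CellAtlas) -> CellQC:
    """Detected genes, mitochondrial fraction and total counts per cell.

    An all-zero cell has undefined mitochondrial fraction; it is reported as
    0 with a warning (such cells fail the detected-genes filter anyway).
    """
    if "mito" not in atlas.gene_meta.columns:
        raise ValueError("gene_meta must carry a 'mito' flag column")
    X = atlas.counts.tocsc()
    detected = np.asarray((X > 0).sum(axis=0)).ravel()
    totals = np.asarray(X.sum(axis=0)).ravel().astype(float)
    mito_mask = atlas.gene_meta["mito"].to_numpy()
    mito_counts = np.asarray(X[mito_mask, :].sum(axis=0)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning("%d all-zero cells; mito_fraction set to 0", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(zero, 0.0, mito_counts / np.where(zero, 1.0, totals))
    table = pd.DataFrame(
        {
            "detected_genes": detected.astype(int),
            "mito_fraction": mito_frac,
            "total_counts": totals,
        },
        index=atlas.cell_meta.index if len(atlas.cell_meta) else None,
    )
    return CellQC(table=table)


def filter_cells(
    atlas: CellAtlas,
    qc: CellQC | None = None,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito: float = 0.10,
) -> CellAtlas:
    """Drop cells failing QC; boundary values are retained.

    A cell is kept iff ``min_genes <= detected <= max_genes`` and
    ``mito_fraction <= max_mito`` (the exclusion rule uses strict
    inequalities, so equality passes).  Filtering is idempotent.  Raises if
    no cell survives.
    """
    if not (0 < min_genes < max_genes):
        raise ValueError("need 0 < min_genes < max_genes")
    if qc is None:
        qc = compute_cell_qc(atlas)
    t = qc.table
    keep = (
        (t["detected_genes"].to_numpy() >= min_genes)
        & (t["detected_genes"].to_numpy() <= max_genes)
        & (t["mito_fraction"].to_numpy() <= max_mito)
    )
    if not keep.any():
        raise ValueError("no cells pass QC thresholds")
    if (~keep).any():
        logger.info("QC removed %d of %d cells", int((~keep).sum()), keep.size)
    return atlas.subset_cells(keep)


def log_normalize(atlas: CellAtlas, scale: float = 1e4) -> sp.csr_matrix:
    """LogNormalize: ln(1 + count / cell_total * scale), natural log.

    Zero counts stay exactly zero (sparse structure preserved); values are
    invariant to rescaling all counts within a cell.
    """
    X = atlas.counts.tocsc().astype(float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if np.any(totals == 0):
        raise ValueError("cannot normalize all-zero cells; run QC first")
    X = X.multiply(scale / totals[None, :]).tocsr()
    X.data = np.log1p(X.data)
    return X


def _vst_standardized_variance(counts: sp.spmatrix, span: float = 0.3) -> np.ndarray:
    """Per-gene standardized variance after trend correction (vst recipe).

    Fits log10(variance) on log10(mean) of raw counts with lowess (local
    polynomial fallback for tiny fixtures), then computes the variance of
    counts standardized by the trend-predicted sd and clipped at sqrt(N).
    Genes with zero mean or zero variance get standardized variance 0.
    """
    X = counts.tocsr().astype(float)
    n_genes, n_cells = X.shape
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n_cells / max(n_cells - 1, 1)

    usable = (mean > 0) & (var > 0)
    if not usable.any():
        return np.zeros(n_genes)
    lx = np.log10(mean[usable])
    ly = np.log10(var[usable])
    if usable.sum() >= 50 and np.unique(lx).size >= 10:
        fitted = lowess(ly, lx, frac=span, return_sorted=True)
        pred = np.interp(np.log10(np.clip(mean, 1e-12, None)), fitted[:, 0],
                         fitted[:, 1])
    else:
        deg = min(2, max(1, np.unique(lx).size - 1))
        coef = np.polyfit(lx, ly, deg=deg)
        pred = np.polyval(coef, np.log10(np.clip(mean, 1e-12, None)))
    sd_pred = np.sqrt(10.0**pred)

    clip = np.sqrt(n_cells)
    std_var = np.zeros(n_genes)
    # chunk over genes to bound dense memory
    chunk = max(1, int(2e7 // max(n_cells, 1)))
    for start in range(0, n_genes, chunk):
        stop = min(start + chunk, n_genes)
        block = np.asarray(X[start:stop, :].todense())
        sdb = sd_pred[start:stop]
        ok = usable[start:stop] & (sdb > 0)
        z = np.zeros_like(block)
        z[ok] = (block[ok] - mean[start:stop][ok, None]) / sdb[ok, None]
        np.clip(z, -clip, clip, out=z)
        std_var[start:stop] = np.where(ok, z.var(axis=1, ddof=1), 0.0)
    return std_var


def select_variable_genes(atlas: CellAtlas, n: int = 2000) -> list[str]:
    """Top-``n`` highly variable genes by vst standardized variance.

    Returns gene symbols ranked by decreasing standardized variance; ties and
    zero-variance genes sort last (stable by gene order).
    """
    if n > atlas.n_genes:
        raise ValueError(f"requested {n} variable genes but atlas has {atlas.n_genes}")
    std_var = _vst_standardized_variance(atlas.counts)
    order = np.argsort(-std_var, kind="stable")
    return [atlas.gene_names[i] for i in order[:n]]


def scale_and_pca(
    norm: sp.spmatrix,
    gene_names,
    genes: list[str],
    n_pcs: int = 30,
    clip: float = 10.0,
    randomized_threshold: int = 2_000_000,
) -> np.ndarray:
    """Z-score selected genes (|z| clipped) and embed cells by PCA.

    Returns a cells x n_pcs embedding with components ordered by decreasing
    explained variance and a deterministic sign convention: within each
    component the largest-magnitude gene loading is positive.  Exact SVD is
    used for desk-scale matrices; a seeded randomized solver above
    ``randomized_threshold`` matrix entries.
    """
    gene_names = list(gene_names)
    idx = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in genes if g not in idx]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    rows = [idx[g] for g in genes]
    X = np.asarray(sp.csr_matrix(norm)[rows, :].todense(), dtype=float).T  # cells x genes
    n_cells, n_genes = X.shape
    n_pcs = min(n_pcs, n_cells - 1, n_genes)
    if n_pcs < 1:
        raise ValueError("not enough cells/genes for PCA")

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("degenerate input: all selected genes constant")
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip, clip)
    Zc = Z - Z.mean(axis=0)

    if Zc.size <= randomized_threshold:
        U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    else:
        from sklearn.utils.extmath import randomized_svd

        U, S, Vt = randomized_svd(Zc, n_components=n_pcs, random_state=0)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    # sign convention: largest-|loading| gene positive per component
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    return U * S[None, :]
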