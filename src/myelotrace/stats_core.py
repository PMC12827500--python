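"""Shared statistical primitives with pinned conventions.

All hypothesis tests in the pipeline route through this module so that
edge-case behaviour (zero variance, star thresholds, BH ordering) is defined
in exactly one place.  Tests are two-sided throughout: the upstream analyses
never state sidedness, and two-sided is the conservative default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "student_t", "bh_adjust", "star_label"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample location test.

    ``statistic`` is signed so that a positive value means ``mean(x) > mean(y)``;
    swapping the groups flips the sign but leaves ``pvalue`` unchanged.
    """

    statistic: float
    df: float
    pvalue: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int


def student_t(x, y, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t-test.

    Parameters
    ----------
    x, y
        Real-valued sample vectors, each of length >= 2.
    equal_var
        If True (default) use the pooled-variance Student's t; otherwise
        Welch's t with Satterthwaite degrees of freedom.

    Conventions for degenerate inputs: if both groups have zero variance and
    equal means the test is uninformative and ``p = 1``; zero variance with
    unequal means is the infinite-evidence limit, ``p = 0`` (a warning is
    emitted since this usually indicates constant, noise-free input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError(f"each group needs >= 2 observations, got {nx} and {ny}")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)

    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return TestResult(0.0, float(nx + ny - 2), 1.0, mx, my, nx, ny)
        warnings.warn(
            "zero within-group variance with unequal means; p-value is the "
            "limiting value 0",
            RuntimeWarning,
            stacklevel=2,
        )
        stat = np.inf if mx > my else -np.inf
        return TestResult(float(stat), float(nx + ny - 2), 0.0, mx, my, nx, ny)

    if equal_var:
        df = nx + ny - 2
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    else:
        sex2, sey2 = vx / nx, vy / ny
        se = np.sqrt(sex2 + sey2)
        df = (sex2 + sey2) ** 2 / (
            sex2**2 / (nx - 1) + sey2**2 / (ny - 1)
        )
    t = (mx - my) / se
    p = 2.0 * _sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), mx, my, nx, ny)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Returns adjusted values in the input order, clipped at 1 and
    monotone-enforced.  Adjusted values are always >= the raw values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def star_label(p: float) -> str:
    """Significance star label with strict thresholds.

    ``***`` for p < 0.001, ``**`` for p < 0.01, ``*`` for p < 0.05, otherwise
    the empty string.  Boundary values get the weaker label (p = 0.05 -> "").
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of range: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
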