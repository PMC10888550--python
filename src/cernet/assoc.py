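"""Correlation screens and the wood-volume allometric formula.

Two screens mirror the study design: an expression-expression screen between
RNA classes (|r| > 0.8, p < 0.01, both strict) and an expression-phenotype
screen against a growth trait (|r| > 0.6, p < 0.05).  Pearson correlation
with a two-tailed p-value from the t-transform on n-2 degrees of freedom is
the default; Spearman is available as an option.  No multiple-testing
correction is applied by default (raw thresholds, as in the source screens);
pass ``adjust=True`` to BH-adjust within a screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import ExpressionMatrix

__all__ = [
    "CorrelationResult",
    "pearson_with_p",
    "pearson_p_from_r",
    "expression_correlation",
    "phenotype_correlation",
    "volume_of_wood",
]

#: coefficients of the species-specific allometric volume equation
#: VW [m^3] = A * DBH[cm]^B * HT[m]^C
VW_COEF = 6.01228e-5
VW_DBH_EXP = 1.8755
VW_HT_EXP = 0.98496


@dataclass(frozen=True)
class CorrelationResult:
    id_a: str
    id_b: str
    r: float
    p: float
    n: int


def pearson_with_p(x, y, method: str = "pearson") -> tuple[float, float, int]:
    """Correlation coefficient with two-tailed p-value and sample size.

    Raises on n < 3 or zero variance in either vector (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), n


def pearson_p_from_r(r, n) -> np.ndarray:
    """Two-tailed p from the t-transform t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    r = np.asarray(r, dtype=float)
    if np.any(n < 3):
        raise ValueError("need n >= 3")
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rr) >= 1.0, 0.0, p)


def _passes(r: float, p: float, r_min: float, p_max: float) -> bool:
    """Strict-threshold rule shared by both screens: |r| > r_min AND p < p_max."""
    return abs(r) > r_min and p < p_max


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of ``a`` and every row of ``b``."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(asd, bsd)
    return r


def expression_correlation(
    mat_a: ExpressionMatrix | pd.DataFrame,
    mat_b: ExpressionMatrix | pd.DataFrame,
    r_min: float = 0.8,
    p_max: float = 0.01,
    method: str = "pearson",
    adjust: bool = False,
) -> list[CorrelationResult]:
    """All cross-class RNA pairs with |r| > r_min and p < p_max (strict)."""
    a = mat_a.values if isinstance(mat_a, ExpressionMatrix) else mat_a
    b = mat_b.values if isinstance(mat_b, ExpressionMatrix) else mat_b
    if list(a.columns) != list(b.columns):
        raise ValueError("matrices must share an identical sample set/order")
    n = a.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    av, bv = a.to_numpy(float), b.to_numpy(float)
    if method == "spearman":
        av = stats.rankdata(av, axis=1)
        bv = stats.rankdata(bv, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r = _row_correlations(av, bv)
    valid = ~np.isnan(r)
    p = np.ones_like(r)
    p[valid] = pearson_p_from_r(r[valid], n)
    if adjust:
        p_flat = p[valid]
        p[valid] = bh_adjust(p_flat)
    hits = []
    ii, jj = np.nonzero(valid & (np.abs(r) > r_min) & (p < p_max))
    for i, j in zip(ii, jj):
        hits.append(
            CorrelationResult(str(a.index[i]), str(b.index[j]),
                              float(r[i, j]), float(p[i, j]), n)
        )
    return hits


def phenotype_correlation(
    matrix: ExpressionMatrix | pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait: str = "VW",
    r_min: float = 0.6,
    p_max: float = 0.05,
    method: str = "pearson",
    adjust: bool = False,
) -> dict[str, list[CorrelationResult]]:
    """Per-RNA correlation against one trait; signed hit lists.

    ``trait`` is HT, DBH or VW (phenotype table columns HT_m / DBH_cm / VW_m3).
    Returns ``{"positive": [...], "negative": [...]}``.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    col = {"HT": "HT_m", "DBH": "DBH_cm", "VW": "VW_m3"}.get(trait, trait)
    if col not in phenotypes.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    missing = [s for s in values.columns if s not in phenotypes.index]
    if missing:
        raise ValueError(f"phenotype missing for samples {missing}")
    y = phenotypes.loc[list(values.columns), col].to_numpy(float)
    n = values.shape[1]
    xv = values.to_numpy(float)
    if method == "spearman":
        xv = stats.rankdata(xv, axis=1)
        yv = stats.rankdata(y)
    else:
        yv = y
    r = _row_correlations(xv, yv[None, :]).ravel()
    valid = ~np.isnan(r)
    p = np.ones_like(r)
    p[valid] = pearson_p_from_r(r[valid], n)
    if adjust:
        p[valid] = bh_adjust(p[valid])
    out: dict[str, list[CorrelationResult]] = {"positive": [], "negative": []}
    for i in np.nonzero(valid)[0]:
        if _passes(r[i], p[i], r_min, p_max):
            side = "positive" if r[i] > 0 else "negative"
            out[side].append(
                CorrelationResult(str(values.index[i]), trait,
                                  float(r[i]), float(p[i]), n)
            )
    return out


def volume_of_wood(dbh, ht):
    """Wood volume (m^3) from DBH (cm) and height (m) by the allometric
    equation VW = 6.01228e-5 * DBH^1.8755 * HT^0.98496."""
    dbh = np.asarray(dbh, dtype=float)
    ht = np.asarray(ht, dtype=float)
    if (dbh < 0).any() or (ht < 0).any():
        raise ValueError("DBH and HT must be non-negative")
    vw = VW_COEF * dbh**VW_DBH_EXP * ht**VW_HT_EXP
    return vw if vw.ndim else float(vw)
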