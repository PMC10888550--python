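"""Pairwise differential expression between two single individuals.

The study design compares single trees, so there are no biological replicates
and the dispersion of the negative-binomial count model cannot be estimated
from the data.  This module therefore implements one defined test: a
conditional exact test with a fixed, user-supplied dispersion.  Conditioning
the test-sample count on the pair total makes the null distribution free of
the unknown mean; at dispersion 0 the negative binomial degenerates to a
Poisson and the conditional law is exactly Binomial(total, s_t/(s_t+s_r)).

Two-sidedness follows the probability-mass rule used by classical exact
count tests: the p-value is the summed probability of all outcomes no more
likely than the observed one.

An RNA is called differentially expressed at |log2FC| > 1 and p < 0.05
(strict inequalities); Benjamini-Hochberg q-values are reported alongside
and can optionally drive the call instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "DeParams",
    "ComparisonResult",
    "log2_fold_change",
    "nb_exact_test",
    "bh_adjust",
    "classify_status",
    "size_factors",
    "call_de",
]


@dataclass
class DeParams:
    """Thresholds and model constants for the no-replicate DE call."""

    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    dispersion: float = 0.1  # NB overdispersion (var = mu + d*mu^2)
    pseudocount: float = 1.0  # added on the normalized scale for log2FC
    use_q: bool = False  # apply p_threshold to BH q instead of raw p

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class ComparisonResult:
    """Per-RNA DE results for one (reference, test) sample pair."""

    reference: str
    test: str
    rna_class: str
    table: pd.DataFrame  # index rna_id; count_ref count_test log2fc p q status


def log2_fold_change(value_test, value_ref, pseudocount: float = 1.0):
    """log2((test + pc) / (ref + pc)); direction is test relative to reference."""
    vt = np.asarray(value_test, dtype=float)
    vr = np.asarray(value_ref, dtype=float)
    if (vt < 0).any() or (vr < 0).any():
        raise ValueError("expression values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(vt + pseudocount) - np.log2(vr + pseudocount)
    # 0/0 with pseudocount 0: no change by convention
    lfc = np.where((vt == vr), 0.0, lfc)
    return lfc if lfc.ndim else float(lfc)


def _conditional_log_weights(
    total: int, size_test: float, size_ref: float, dispersion: float
) -> np.ndarray:
    """Log conditional null weights of the test count given the pair total.

    Dispersion 0: Binomial(total, s_t/(s_t+s_r)).  Dispersion > 0: product of
    two NB pmfs with a common underlying mean, normalized over all splits; the
    common mean is taken as total/(s_t+s_r) (it cancels entirely when the size
    factors are equal).
    """
    k = np.arange(total + 1)
    if dispersion == 0.0:
        frac = size_test / (size_test + size_ref)
        return stats.binom.logpmf(k, total, frac)
    r = 1.0 / dispersion
    mu = total / (size_test + size_ref)
    mu_t, mu_r = mu * size_test, mu * size_ref
    # rising-factorial term lgamma(k+r)-lgamma(r) as a cumulative log-sum:
    # stable for arbitrarily large r (vanishing dispersion), where the
    # direct lgamma difference loses ~1e-5 of precision
    rise = np.concatenate(([0.0], np.cumsum(np.log(r + np.arange(total)))))
    logfact = gammaln(k + 1.0)
    log1mp_t = np.log(mu_t) - np.log(r + mu_t)  # log(1 - p_test)
    log1mp_r = np.log(mu_r) - np.log(r + mu_r)
    logw = (
        rise[k] - logfact
        + rise[total - k] - logfact[::-1]
        + k * log1mp_t + (total - k) * log1mp_r
    )
    return logw - logsumexp(logw)


def nb_exact_test(
    count_test: int,
    count_ref: int,
    size_factor_test: float = 1.0,
    size_factor_ref: float = 1.0,
    dispersion: float = 0.0,
) -> float:
    """Two-sided conditional exact p-value for a single RNA.

    Sums the conditional null probabilities of all splits of the pair total
    whose probability does not exceed that of the observed split.
    """
    if count_test < 0 or count_ref < 0:
        raise ValueError("counts must be non-negative")
    if int(count_test) != count_test or int(count_ref) != count_ref:
        raise ValueError("counts must be integers")
    if size_factor_test <= 0 or size_factor_ref <= 0:
        raise ValueError("size factors must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    total = int(count_test) + int(count_ref)
    if total == 0:
        return 1.0
    logw = _conditional_log_weights(
        total, size_factor_test, size_factor_ref, dispersion
    )
    w = np.exp(logw - logw.max())
    w /= w.sum()
    obs = w[int(count_test)]
    # 1+1e-12 guards against ties lost to rounding (as in Fisher-type tests)
    return float(min(1.0, w[w <= obs * (1 + 1e-12)].sum()))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1.

    Output is aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_status(log2fc, p, params: DeParams, q=None) -> np.ndarray:
    """up / down / ns per the strict-threshold rule.

    ``up`` iff log2fc > lfc_threshold and p < p_threshold; ``down`` mirrored.
    With ``params.use_q`` the significance threshold applies to q instead.
    """
    lfc = np.atleast_1d(np.asarray(log2fc, dtype=float))
    crit = np.atleast_1d(np.asarray(q if params.use_q else p, dtype=float))
    status = np.full(lfc.shape, "ns", dtype=object)
    sig = crit < params.p_threshold
    status[(lfc > params.lfc_threshold) & sig] = "up"
    status[(lfc < -params.lfc_threshold) & sig] = "down"
    return status


def size_factors(counts: pd.DataFrame, method: str = "median-of-ratios") -> pd.Series:
    """Per-sample size factors, normalized to mean 1.

    Default is the median-of-ratios estimator (median over genes of the count
    over its across-sample geometric mean), which is robust to composition
    bias when a few strongly regulated RNAs dominate a library.  ``"total"``
    uses the column sum over the mean column sum; it falls over exactly in
    that strongly-regulated regime and is kept for comparison.
    """
    if method == "total":
        totals = counts.sum(axis=0).astype(float)
        if (totals <= 0).any():
            raise ValueError("every sample must have a positive total count")
        return totals / totals.mean()
    if method != "median-of-ratios":
        raise ValueError(f"unknown size-factor method {method!r}")
    arr = counts.to_numpy(float)
    mask = (arr > 0).all(axis=1)
    if not mask.any():
        return size_factors(counts, method="total")
    logc = np.log(arr[mask])
    logratio = logc - logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logratio, axis=0))
    sf = sf / sf.mean()
    return pd.Series(sf, index=counts.columns)


def call_de(
    counts: pd.DataFrame,
    reference_sample: str,
    test_sample: str,
    params: DeParams | None = None,
    rna_class: str = "mRNA",
    sample_size_factors: pd.Series | None = None,
) -> ComparisonResult:
    """Per-RNA DE call between two samples of an integer count matrix."""
    params = params or DeParams()
    for s in (reference_sample, test_sample):
        if s not in counts.columns:
            raise KeyError(f"sample {s!r} not in count matrix")
    sf = size_factors(counts) if sample_size_factors is None else sample_size_factors
    s_ref = float(sf[reference_sample])
    s_test = float(sf[test_sample])

    c_ref = counts[reference_sample].to_numpy()
    c_test = counts[test_sample].to_numpy()
    lfc = log2_fold_change(c_test / s_test, c_ref / s_ref, params.pseudocount)

    cache: dict[int, np.ndarray] = {}
    pvals = np.empty(len(counts))
    for i, (ct, cr) in enumerate(zip(c_test, c_ref)):
        total = int(ct) + int(cr)
        if total == 0:
            pvals[i] = 1.0
            continue
        w = cache.get(total)
        if w is None:
            logw = _conditional_log_weights(total, s_test, s_ref, params.dispersion)
            w = np.exp(logw - logw.max())
            w /= w.sum()
            cache[total] = w
        obs = w[int(ct)]
        pvals[i] = min(1.0, w[w <= obs * (1 + 1e-12)].sum())

    q = bh_adjust(pvals)
    status = classify_status(lfc, pvals, params, q=q)
    table = pd.DataFrame(
        {
            "count_ref": c_ref.astype(int),
            "count_test": c_test.astype(int),
            "log2fc": lfc,
            "p": pvals,
            "q": q,
            "status": status,
        },
        index=counts.index.copy(),
    )
    table.index.name = "rna_id"
    return ComparisonResult(reference_sample, test_sample, rna_class, table)
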