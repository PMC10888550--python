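"""Relative expression by the 2^-ddCt method with multi-reference-gene
normalization.

dCt(sample) = mean replicate Ct(target) - normalizer Ct, where the normalizer
is the mean of the reference genes' mean Cts (for a single reference gene,
its mean Ct; averaging Cts is geometric-mean normalization on the linear
scale).  ddCt = dCt(sample) - dCt(calibrator); relative expression = 2^-ddCt,
so the calibrator sample is exactly 1.  A per-reference mode computes one
profile per reference gene instead of the combined estimator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import CorrelationResult, pearson_with_p

__all__ = ["relative_expression", "validation_correlation", "mean_ct"]


def _check_table(table: pd.DataFrame) -> None:
    required = {"gene", "sample", "replicate", "Ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    if (table["Ct"] <= 0).any():
        raise ValueError("Ct values must be positive")


def mean_ct(table: pd.DataFrame, gene: str) -> pd.Series:
    """Replicate-averaged Ct per sample for one gene."""
    sub = table[table["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} not in qPCR table")
    return sub.groupby("sample")["Ct"].mean()


def relative_expression(
    table: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
    calibrator_sample: str,
    per_reference: bool = False,
) -> pd.Series | pd.DataFrame:
    """Per-sample 2^-ddCt relative expression of ``target_gene``.

    Returns a Series indexed by sample, or with ``per_reference`` a DataFrame
    (samples x reference genes) of per-reference-gene profiles.
    """
    _check_table(table)
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    target_ct = mean_ct(table, target_gene)
    ref_cts = pd.DataFrame({g: mean_ct(table, g) for g in reference_genes})
    if calibrator_sample not in target_ct.index:
        raise KeyError(f"calibrator sample {calibrator_sample!r} not measured")
    missing = ref_cts.index.symmetric_difference(target_ct.index)
    if len(missing):
        raise KeyError(f"samples not measured for all genes: {list(missing)}")

    def rel(normalizer: pd.Series) -> pd.Series:
        dct = target_ct - normalizer
        ddct = dct - dct[calibrator_sample]
        return np.power(2.0, -ddct)

    if per_reference:
        return pd.DataFrame({g: rel(ref_cts[g]) for g in reference_genes})
    return rel(ref_cts.mean(axis=1))


def validation_correlation(
    relexp: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait: str = "VW",
) -> tuple[list[CorrelationResult], dict[str, str]]:
    """Pearson correlation of per-gene relative expression against a trait.

    ``relexp`` is samples x genes.  Genes whose correlation is undefined
    (constant expression) are reported in the returned error map and the run
    continues.
    """
    col = {"HT": "HT_m", "DBH": "DBH_cm", "VW": "VW_m3"}.get(trait, trait)
    if col not in phenotypes.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    y = phenotypes.loc[list(relexp.index), col].to_numpy(float)
    results: list[CorrelationResult] = []
    errors: dict[str, str] = {}
    for gene in relexp.columns:
        try:
            r, p, n = pearson_with_p(relexp[gene].to_numpy(float), y)
        except ValueError as exc:
            errors[str(gene)] = str(exc)
            continue
        results.append(CorrelationResult(str(gene), trait, r, p, n))
    return results, errors
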