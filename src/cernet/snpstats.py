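"""Minor-allele-frequency filtering and transition/transversion statistics.

SNPs called from RNA-seq across the ten individuals are filtered at
MAF >= 0.1 (inclusive), then classified into the six unordered substitution
types.  Transitions are purine<->purine or pyrimidine<->pyrimidine (A/G, C/T);
the four remaining types are transversions.  The report mirrors the published
frequency table: per-type counts, percentages to two decimals, class totals
and the transition/transversion ratio.

MAF is allele-count based over called genotypes: missing genotypes are
excluded from the denominator and half-calls contribute their one called
allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SnpRecord

__all__ = [
    "TsTvTable",
    "minor_allele_frequency",
    "maf_filter",
    "classify_substitution",
    "tstv_table",
    "tstv_table_from_counts",
    "SUBSTITUTION_TYPES",
]

#: unordered substitution types in report order (transitions first)
SUBSTITUTION_TYPES = ("C/T", "A/G", "A/T", "A/C", "G/T", "G/C")
TRANSITION_TYPES = ("C/T", "A/G")

_NUCS = frozenset("ACGT")


def minor_allele_frequency(record: SnpRecord) -> float:
    """min(alt, ref allele count) / called alleles; error if all missing."""
    g = record.genotypes
    called = g[g >= 0]
    if called.size == 0:
        raise ValueError(
            f"{record.chrom}:{record.pos}: MAF undefined, all genotypes missing"
        )
    alt = int((called == 1).sum())
    return min(alt, called.size - alt) / called.size


def maf_filter(
    snps: Iterable[SnpRecord], min_maf: float = 0.1
) -> list[SnpRecord]:
    """Keep records with MAF >= min_maf (inclusive boundary)."""
    return [s for s in snps if minor_allele_frequency(s) >= min_maf]


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """(category, unordered type) for a ref->alt substitution.

    Orientation-independent: (A, G) and (G, A) are both transitions of type
    "A/G".
    """
    if ref not in _NUCS or alt not in _NUCS:
        raise ValueError(f"invalid nucleotides {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    pair = frozenset((ref, alt))
    for t in SUBSTITUTION_TYPES:
        a, b = t.split("/")
        if pair == frozenset((a, b)):
            category = "transition" if t in TRANSITION_TYPES else "transversion"
            return category, t
    raise AssertionError("unreachable")


@dataclass
class TsTvTable:
    """Counts and frequencies for the six unordered substitution types."""

    counts: dict[str, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def transition_total(self) -> int:
        return sum(self.counts[t] for t in TRANSITION_TYPES)

    @property
    def transversion_total(self) -> int:
        return self.n - self.transition_total

    @property
    def frequencies(self) -> dict[str, float]:
        """Per-type percentage of all sites (unrounded)."""
        n = self.n
        if n == 0:
            return {t: float("nan") for t in SUBSTITUTION_TYPES}
        return {t: 100.0 * self.counts[t] / n for t in SUBSTITUTION_TYPES}

    @property
    def frequencies_pct(self) -> dict[str, float]:
        """Per-type percentages rounded to 2 decimals, as reported."""
        return {t: round(f, 2) for t, f in self.frequencies.items()}

    @property
    def transition_pct(self) -> float:
        return round(100.0 * self.transition_total / self.n, 2) if self.n else float("nan")

    @property
    def transversion_pct(self) -> float:
        return round(100.0 * self.transversion_total / self.n, 2) if self.n else float("nan")

    @property
    def ratio(self) -> float:
        """Ts/Tv ratio, unrounded; inf when no transversions were seen."""
        if self.n == 0:
            return float("nan")
        if self.transversion_total == 0:
            return float("inf")
        return self.transition_total / self.transversion_total

    @property
    def ratio_2dp(self) -> float:
        return round(self.ratio, 2)

    @property
    def is_empty(self) -> bool:
        return self.n == 0

    def to_frame(self) -> pd.DataFrame:
        """Report-shaped table: one row per type plus class totals."""
        rows = [
            (
                t,
                "transition" if t in TRANSITION_TYPES else "transversion",
                self.counts[t],
                self.frequencies_pct[t],
            )
            for t in SUBSTITUTION_TYPES
        ]
        return pd.DataFrame(
            rows, columns=["type", "category", "count", "frequency_pct"]
        )

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "frequencies_pct": self.frequencies_pct,
            "transition_total": self.transition_total,
            "transversion_total": self.transversion_total,
            "transition_pct": self.transition_pct,
            "transversion_pct": self.transversion_pct,
            "total": self.n,
            "ratio": None if self.is_empty else self.ratio_2dp,
        }


def tstv_table_from_counts(counts: Mapping[str, int]) -> TsTvTable:
    """Build the frequency report directly from per-type allelic-site counts."""
    full = {t: int(counts.get(t, 0)) for t in SUBSTITUTION_TYPES}
    extra = set(counts) - set(SUBSTITUTION_TYPES)
    if extra:
        raise ValueError(f"unknown substitution types {sorted(extra)}")
    return TsTvTable(full)


def tstv_table(snps: Sequence[SnpRecord]) -> TsTvTable:
    """Classify records and report counts, frequencies and the Ts/Tv ratio."""
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    for s in snps:
        _, t = classify_substitution(s.ref_allele, s.alt_allele)
        counts[t] += 1
    return TsTvTable(counts)
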