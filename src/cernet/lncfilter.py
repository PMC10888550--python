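"""Candidate lncRNA filtering on assembled transcripts.

Three rules, applied in order:

1. expression: remove transcripts with FPKM < 0.5 (boundary retained);
2. structure: remove short (< 200 bp summed exon length) or single-exon
   transcripts — i.e. retain only transcripts satisfying both minima, the
   standard lncRNA definition (the opposite reading, remove only when both
   conditions hold, is exposed via ``short_rule="both"``);
3. position: remove transcripts whose genomic span overlaps the 1-kb flanking
   window of any annotated gene on the same chromosome (strand-agnostic).

The retained set is the intersection of the three per-rule retained sets;
rule order affects only which rule a removed transcript is attributed to.
Coding-potential filtering is accepted as a pre-computed id blacklist rather
than recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import GeneAnnotation, TranscriptRecord

__all__ = [
    "FilterParams",
    "FilterReport",
    "filter_low_expression",
    "filter_short",
    "filter_near_genes",
    "filter_lncrna_candidates",
]


@dataclass
class FilterParams:
    min_fpkm: float = 0.5
    min_len: int = 200
    min_exons: int = 2
    flank: int = 1000
    short_rule: str = "any"  # "any": remove if short OR single-exon

    def __post_init__(self) -> None:
        if self.short_rule not in ("any", "both"):
            raise ValueError("short_rule must be 'any' or 'both'")


@dataclass
class FilterReport:
    """Per-rule removal counts; each transcript is attributed to the first
    rule (in 1->2->3 order) that removed it."""

    n_input: int
    removed_low_expression: int
    removed_short: int
    removed_near_gene: int
    removed_blacklist: int
    n_retained: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _passes_expression(t: TranscriptRecord, min_fpkm: float) -> bool:
    return t.fpkm >= min_fpkm


def _passes_structure(
    t: TranscriptRecord, min_len: int, min_exons: int, short_rule: str
) -> bool:
    if short_rule == "any":
        return t.length >= min_len and t.exon_count >= min_exons
    # "both": removed only when short AND single-exon
    return t.length >= min_len or t.exon_count >= min_exons


def _passes_position(
    t: TranscriptRecord, genes_by_chrom: dict[str, list[tuple[int, int]]], flank: int
) -> bool:
    # half-open 0-based internally; GTF interface is 1-based inclusive
    t0, t1 = t.start - 1, t.end
    for g0, g1 in genes_by_chrom.get(t.chrom, ()):
        if t0 < g1 + flank and g0 - flank < t1:
            return False
    return True


def _index_genes(genes: Iterable[GeneAnnotation]) -> dict[str, list[tuple[int, int]]]:
    idx: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        idx.setdefault(g.chrom, []).append((g.start - 1, g.end))
    return idx


def filter_low_expression(
    transcripts: Iterable[TranscriptRecord], min_fpkm: float = 0.5
) -> list[TranscriptRecord]:
    """Keep transcripts with FPKM >= min_fpkm."""
    return [t for t in transcripts if _passes_expression(t, min_fpkm)]


def filter_short(
    transcripts: Iterable[TranscriptRecord],
    min_len: int = 200,
    min_exons: int = 2,
    short_rule: str = "any",
) -> list[TranscriptRecord]:
    """Keep transcripts meeting the length and exon-count minima."""
    return [
        t
        for t in transcripts
        if _passes_structure(t, min_len, min_exons, short_rule)
    ]


def filter_near_genes(
    transcripts: Iterable[TranscriptRecord],
    genes: Iterable[GeneAnnotation],
    flank: int = 1000,
) -> list[TranscriptRecord]:
    """Remove transcripts overlapping [gene.start - flank, gene.end + flank]
    on the same chromosome (strand-agnostic, genomic span)."""
    idx = _index_genes(genes)
    return [t for t in transcripts if _passes_position(t, idx, flank)]


def filter_lncrna_candidates(
    transcripts: Sequence[TranscriptRecord],
    genes: Iterable[GeneAnnotation],
    params: FilterParams | None = None,
    coding_blacklist: Iterable[str] | None = None,
) -> tuple[list[TranscriptRecord], FilterReport]:
    """Apply the three rules in order and report per-rule removal counts.

    An optional ``coding_blacklist`` of transcript ids (pre-computed
    coding-potential calls) is applied first.
    """
    params = params or FilterParams()
    blacklist = set(coding_blacklist or ())
    idx = _index_genes(genes)
    retained: list[TranscriptRecord] = []
    n_black = n_expr = n_short = n_near = 0
    for t in transcripts:
        if t.transcript_id in blacklist:
            n_black += 1
        elif not _passes_expression(t, params.min_fpkm):
            n_expr += 1
        elif not _passes_structure(
            t, params.min_len, params.min_exons, params.short_rule
        ):
            n_short += 1
        elif not _passes_position(t, idx, params.flank):
            n_near += 1
        else:
            retained.append(t)
    report = FilterReport(
        n_input=len(transcripts),
        removed_low_expression=n_expr,
        removed_short=n_short,
        removed_near_gene=n_near,
        removed_blacklist=n_black,
        n_retained=len(retained),
    )
    return retained, report
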