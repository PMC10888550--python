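"""Readers and writers for every external format the pipeline touches.

Tab-separated expression matrices (RNAs x samples), two-column-plus target
maps, phenotype tables, qPCR Ct tables, exon-bearing GTF annotation, VCF v4.2
variant tables, and GraphML / edge-list exports of assembled networks.

Conventions
-----------
* GTF coordinates are 1-based inclusive at the interface; interval arithmetic
  inside the package is half-open 0-based and converts at this boundary.
* All readers validate and reject malformed input rather than silently coerce.
* Every writer/reader pair round-trips valid data exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")

#: abundance unit each RNA class carries when mirroring the source study:
#: FPKM for the rRNA-depleted libraries (mRNA, lncRNA), TPM for the
#: small-RNA / back-splice libraries (miRNA, circRNA).
UNIT_FOR_CLASS = {"mRNA": "FPKM", "lncRNA": "FPKM", "circRNA": "TPM", "miRNA": "TPM"}

VALID_UNITS = ("FPKM", "TPM", "count")


class FormatError(ValueError):
    """Malformed external input (parse or validation failure)."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Abundance values for one RNA class across samples.

    ``values`` is a pandas DataFrame with RNA ids as the index and sample ids
    as columns; entries are non-negative reals (or integers for counts).
    """

    values: pd.DataFrame
    rna_class: str
    unit: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise FormatError(f"unknown RNA class {self.rna_class!r}")
        if self.unit not in VALID_UNITS:
            raise FormatError(f"unknown unit {self.unit!r}")
        if self.unit != "count" and self.unit != UNIT_FOR_CLASS[self.rna_class]:
            raise FormatError(
                f"{self.rna_class} matrices carry {UNIT_FOR_CLASS[self.rna_class]}, "
                f"not {self.unit}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate RNA ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric expression values")
        if np.isnan(arr).any():
            raise FormatError("missing values in expression matrix")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative value at RNA {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def rna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_expression(path, unit: str, rna_class: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (header row of samples, RNA ids in col 1)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    cols = {}
    for col in raw.columns:
        try:
            cols[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"malformed numeric cell at row {row!r}, column {col!r}"
            ) from exc
    df = pd.DataFrame(cols, index=raw.index)
    df.index.name = "rna_id"
    return ExpressionMatrix(df, rna_class=rna_class, unit=unit)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "rna_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Target pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetPair:
    """A predicted miRNA -> target interaction."""

    mirna_id: str
    target_id: str
    target_class: str  # mRNA, lncRNA or circRNA
    score: float | None = None

    def __post_init__(self) -> None:
        if self.mirna_id == self.target_id:
            raise FormatError("miRNA cannot target itself")
        if self.target_class not in ("mRNA", "lncRNA", "circRNA"):
            raise FormatError(f"invalid target class {self.target_class!r}")


def read_targets(path) -> list[TargetPair]:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "target_id": str})
    pairs = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        if score is not None and (isinstance(score, float) and math.isnan(score)):
            score = None
        pairs.append(
            TargetPair(row.mirna_id, row.target_id, row.target_class, score)
        )
    return pairs


def write_targets(pairs: Iterable[TargetPair], path) -> None:
    df = pd.DataFrame(
        [(p.mirna_id, p.target_id, p.target_class, p.score) for p in pairs],
        columns=["mirna_id", "target_id", "target_class", "score"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV (sample, HT_m, DBH_cm, VW_m3), indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "HT_m", "DBH_cm", "VW_m3"}
    if not required.issubset(df.columns):
        raise FormatError(f"phenotype table must have columns {sorted(required)}")
    if df["sample"].duplicated().any():
        raise FormatError("duplicate sample ids in phenotype table")
    df = df.set_index("sample")
    if (df[["HT_m", "DBH_cm", "VW_m3"]] <= 0).any().any():
        raise FormatError("HT, DBH and VW must be positive")
    return df


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    out = phen.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def read_qpcr(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str})
    required = {"gene", "sample", "replicate", "Ct", "is_reference"}
    if not required.issubset(df.columns):
        raise FormatError(f"qPCR table must have columns {sorted(required)}")
    if (df["Ct"] <= 0).any():
        raise FormatError("Ct values must be positive")
    df["is_reference"] = df["is_reference"].astype(bool)
    return df


def write_qpcr(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


@dataclass
class TranscriptRecord:
    """Assembled transcript aggregated from its exon lines.

    ``length`` is the summed exon length in bp; ``start``/``end`` the genomic
    span, 1-based inclusive.
    """

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_count: int
    length: int
    fpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"{self.transcript_id}: end < start")
        if self.exon_count < 1:
            raise FormatError(f"{self.transcript_id}: exon_count < 1")


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"{self.gene_id}: end < start")


def read_gtf(path) -> tuple[list[TranscriptRecord], list[GeneAnnotation]]:
    """Parse an exon-bearing GTF into transcripts and gene annotations.

    Transcripts are aggregated from exon lines (exon count, summed exon length,
    genomic span, strand).  Genes come from explicit ``gene`` features when
    present, otherwise from the span of each gene_id's exons.  A ``FPKM``
    attribute (as written by common assemblers) is picked up when present.
    """
    import gffutils

    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        return [], []

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    genes: list[GeneAnnotation] = []
    seen_gene_feature = False
    for g in db.features_of_type("gene"):
        seen_gene_feature = True
        gid = (g.attributes.get("gene_id") or [g.id])[0]
        genes.append(GeneAnnotation(gid, g.seqid, g.start, g.end, g.strand))

    tx: dict[str, dict] = {}
    gene_span: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tids = exon.attributes.get("transcript_id")
        if not tids:
            raise FormatError(
                f"exon at {exon.seqid}:{exon.start} lacks transcript_id"
            )
        tid = tids[0]
        rec = tx.setdefault(
            tid,
            {
                "chrom": exon.seqid,
                "start": exon.start,
                "end": exon.end,
                "strand": exon.strand,
                "n": 0,
                "len": 0,
                "fpkm": 0.0,
            },
        )
        rec["start"] = min(rec["start"], exon.start)
        rec["end"] = max(rec["end"], exon.end)
        rec["n"] += 1
        rec["len"] += exon.end - exon.start + 1
        if "FPKM" in exon.attributes:
            rec["fpkm"] = float(exon.attributes["FPKM"][0])
        gids = exon.attributes.get("gene_id")
        if gids and not seen_gene_feature:
            gs = gene_span.setdefault(
                gids[0],
                {"chrom": exon.seqid, "start": exon.start, "end": exon.end,
                 "strand": exon.strand},
            )
            gs["start"] = min(gs["start"], exon.start)
            gs["end"] = max(gs["end"], exon.end)

    for t in db.features_of_type("transcript"):
        tid = (t.attributes.get("transcript_id") or [t.id])[0]
        if tid in tx and "FPKM" in t.attributes:
            tx[tid]["fpkm"] = float(t.attributes["FPKM"][0])

    transcripts = [
        TranscriptRecord(
            tid, r["chrom"], r["start"], r["end"], r["strand"], r["n"],
            r["len"], r["fpkm"],
        )
        for tid, r in tx.items()
    ]
    if not seen_gene_feature:
        genes = [
            GeneAnnotation(gid, s["chrom"], s["start"], s["end"], s["strand"])
            for gid, s in gene_span.items()
        ]
    return transcripts, genes


def write_gtf(
    transcripts: Sequence[TranscriptRecord],
    genes: Sequence[GeneAnnotation],
    path,
) -> None:
    """Write transcripts (one exon line per exon, equal-split lengths) + genes."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tcernet\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
        for t in transcripts:
            # split summed exon length into exon_count contiguous-ish exons
            base = t.length // t.exon_count
            rem = t.length - base * t.exon_count
            pos = t.start
            gap = 0
            span = t.end - t.start + 1
            if t.exon_count > 1:
                gap = max(0, (span - t.length) // (t.exon_count - 1))
            attrs = (
                f'gene_id "{t.transcript_id}_g"; transcript_id "{t.transcript_id}"; '
                f'FPKM "{t.fpkm:.6f}";'
            )
            for i in range(t.exon_count):
                elen = base + (1 if i < rem else 0)
                end = pos + elen - 1
                fh.write(
                    f"{t.chrom}\tcernet\texon\t{pos}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
                pos = end + 1 + gap


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_NUCS = frozenset("ACGT")


@dataclass
class SnpRecord:
    """One biallelic SNP with per-sample diploid genotype calls.

    ``genotypes`` is an (n_samples, 2) integer array of allele indices
    (0 = ref, 1 = alt, -1 = missing).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.ref_allele not in _NUCS or self.alt_allele not in _NUCS:
            raise FormatError(
                f"{self.chrom}:{self.pos}: alleles must be single nucleotides"
            )
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"{self.chrom}:{self.pos}: ref == alt")
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != 2:
            raise FormatError("genotypes must be (n_samples, 2)")


@dataclass
class VcfReadReport:
    n_kept: int = 0
    n_multiallelic: int = 0
    n_indel: int = 0
    n_other: int = 0


def read_vcf(path, n_samples: int | None = None) -> tuple[list[SnpRecord], VcfReadReport]:
    """Read biallelic SNPs from a VCF; indels and multi-allelic sites are
    skipped and counted in the returned report."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    if n_samples is not None and len(vcf.samples) != n_samples:
        raise FormatError(
            f"expected {n_samples} samples, VCF has {len(vcf.samples)}"
        )
    records: list[SnpRecord] = []
    report = VcfReadReport()
    for v in vcf:
        if len(v.ALT) != 1:
            report.n_multiallelic += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            report.n_indel += 1
            continue
        if ref not in _NUCS or alt not in _NUCS:
            report.n_other += 1
            continue
        gts = np.array([[a if a is not None and a >= 0 else -1 for a in g[:2]]
                        for g in v.genotypes], dtype=int)
        records.append(SnpRecord(v.CHROM, v.POS, ref, alt, gts))
        report.n_kept += 1
    return records, report


def write_vcf(records: Sequence[SnpRecord], sample_ids: Sequence[str], path) -> None:
    """Write a minimal deterministic VCF v4.2 with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = []
        for r in records:
            if r.chrom not in chroms:
                chroms.append(r.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for r in records:
            gt_strs = []
            for a, b in r.genotypes:
                gt_strs.append(
                    ("." if a < 0 else str(a)) + "/" + ("." if b < 0 else str(b))
                )
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_strs)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def write_network(net, path, format: str = "tsv") -> None:
    """Export a RegulatoryNetwork as an edge-list TSV or GraphML file."""
    if format == "tsv":
        df = net.edges.copy()
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for row in net.edges.itertuples(index=False):
            g.add_node(row.source, rna_class=row.source_class)
            g.add_node(row.target, rna_class=row.target_class)
            g.add_edge(
                row.source, row.target,
                direction=row.direction, support=int(row.support),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    required = {"source", "source_class", "target", "target_class",
                "direction", "support"}
    if not required.issubset(df.columns):
        raise FormatError(f"edge list must have columns {sorted(required)}")
    return df
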