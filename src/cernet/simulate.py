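"""Deterministic, seedable generator of every input the pipeline consumes.

The generator emulates the study design this package analyses: ten trees on a
graded wood-volume (VW) gradient, whole-transcriptome abundance matrices for
four RNA classes, predicted miRNA-target maps, RNA-seq-derived SNP tables
with a controlled transition/transversion ratio, and qPCR Ct tables.

Planted structure
-----------------
* Phenotypes: height and diameter decrease roughly linearly over the sample
  ranks (with configurable jitter); VW follows exactly from the allometric
  formula, and the extremes are forced so sample SS1 has the maximum VW and
  the last sample the minimum.
* Expression: baselines are log-normal.  Planted DE ncRNAs/mRNAs are elevated
  in high-VW samples by ``effect_log2fc``; planted DE miRNAs are suppressed
  there (the anti-correlated ceRNA layer).  The per-sample effect weight is
  ``((VW - VW_min)/(VW_max - VW_min)) ** gradient_power`` — with the default
  sharp power the effect concentrates on the extreme individual, which is what
  makes an RNA differentially expressed in nearly all nine reference-anchored
  pairs.  Integer pseudo-counts for the exact test are drawn negative-
  binomially around the noisy means.
* ceRNA triples: each planted miRNA anchors one lncRNA-based and one
  circRNA-based triple; the first planted miRNA ("hub") additionally targets
  extra planted mRNAs so degree ranking has a unique winner.
* SNPs: biallelic sites with diploid genotypes; the expected transition
  fraction is ``ts_tv_target / (1 + ts_tv_target)`` and a configurable
  fraction of sites falls below the MAF 0.1 filter boundary.

Every generator draws from its own RNG stream split from the master seed, so
adding one simulation never perturbs another.  Identical configs (including
the seed) give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .assoc import volume_of_wood
from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    SnpRecord,
    TargetPair,
    TranscriptRecord,
)

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "Triple",
    "ExpressionBundle",
    "generate_phenotypes",
    "generate_expression",
    "generate_targets",
    "generate_snps",
    "generate_qpcr",
    "generate_lnc_annotation",
    "simulate_all",
    "REFERENCE_GENES",
]

#: internal reference genes used for qPCR normalization
REFERENCE_GENES = ("CYS", "EF1a", "NADH", "eIF", "ACTIN")

# fixed RNG stream indices (spawned from the master seed)
_STREAM_PHEN, _STREAM_EXPR, _STREAM_TARGETS, _STREAM_SNPS, _STREAM_QPCR, \
    _STREAM_LNC_ANNOT = range(6)


@dataclass
class SimConfig:
    """Stated world of the simulation; defaults mirror the emulated design."""

    n_samples: int = 10
    n_mrna: int = 300
    n_lncrna: int = 200
    n_circrna: int = 80
    n_mirna: int = 60
    n_planted_triples: int = 4  # per ncRNA kind; also the planted-miRNA count
    n_extra_de: int = 8  # extra planted DE RNAs per class (no triple role)
    hub_extra_targets: int = 2  # extra mRNA targets of the hub miRNA, per kind
    n_trait_genes: int = 5  # mRNAs tracking VW linearly
    effect_log2fc: float = 3.0
    dispersion: float = 0.05  # NB overdispersion of the count draws
    noise_sd: float = 0.1  # log2-scale multiplicative noise
    gradient_power: float = 4.0  # sharpness of the extreme-individual effect
    phenotype_jitter: float = 0.03
    seed: int = 0
    ts_tv_target: float = 1.58
    n_sites: int = 5000
    maf_range: tuple[float, float] = (0.1, 0.5)
    maf_below_frac: float = 0.2  # fraction of sites planted below MAF 0.1
    n_decoy_pairs: int = 40  # target pairs among non-DE RNAs
    ct_noise_sd: float = 0.15  # qPCR replicate noise (cycles)
    n_qpcr_replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_mrna", "n_lncrna", "n_circrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0, 0.5]")
        if self.n_planted_triples < 0 or self.n_decoy_pairs < 0:
            raise ValueError("counts must be non-negative")

    def class_sizes(self) -> dict[str, int]:
        return {
            "mRNA": self.n_mrna,
            "lncRNA": self.n_lncrna,
            "circRNA": self.n_circrna,
            "miRNA": self.n_mirna,
        }

    def rng(self, stream: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(6)
        return np.random.default_rng(children[stream])


@dataclass(frozen=True)
class Triple:
    """One planted ceRNA triple: ncRNA sponge, miRNA mediator, mRNA target."""

    ncrna_id: str
    ncrna_class: str  # lncRNA or circRNA
    mirna_id: str
    mrna_id: str


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure, resolvable in every output."""

    elevated: dict[str, list[str]]  # class -> ids elevated in high-VW samples
    suppressed: dict[str, list[str]]
    triples: list[Triple]
    hub_mirna: str
    hub_extra_mrnas: list[str]
    trait_gene_ids: list[str]
    universe: dict[str, list[str]]  # class -> all emitted ids

    def de_ids(self, rna_class: str) -> set[str]:
        return set(self.elevated.get(rna_class, [])) | set(
            self.suppressed.get(rna_class, [])
        )

    def planted_edges(self) -> set[tuple[str, str]]:
        """Undirected (ncRNA-miRNA and miRNA-mRNA) planted interaction pairs."""
        edges: set[tuple[str, str]] = set()
        for t in self.triples:
            edges.add((t.ncrna_id, t.mirna_id))
            edges.add((t.mirna_id, t.mrna_id))
        for m in self.hub_extra_mrnas:
            edges.add((self.hub_mirna, m))
        return edges


@dataclass
class ExpressionBundle:
    """Normalized (FPKM/TPM) and integer count matrices per RNA class."""

    normalized: dict[str, ExpressionMatrix]
    counts: dict[str, ExpressionMatrix]
    lengths: dict[str, pd.Series]


def _sample_ids(n: int) -> list[str]:
    return [f"SS{i + 1}" for i in range(n)]


def generate_phenotypes(config: SimConfig) -> pd.DataFrame:
    """Phenotype table (HT m, DBH cm, VW m^3) on a monotone VW gradient.

    VW is computed exactly from HT and DBH (no noise of its own); SS1 carries
    the maximum VW and the last sample the minimum.
    """
    n = config.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = config.rng(_STREAM_PHEN)
    rank = np.linspace(1.0, 0.0, n)  # SS1 tallest/thickest
    ht = 8.0 + 10.0 * rank
    dbh = 10.0 + 20.0 * rank
    ht = ht * (1.0 + config.phenotype_jitter * rng.normal(size=n))
    dbh = dbh * (1.0 + config.phenotype_jitter * rng.normal(size=n))
    ht = np.clip(ht, 1.0, None)
    dbh = np.clip(dbh, 1.0, None)
    vw = volume_of_wood(dbh, ht)
    # force the extremes to the ends (jitter may have moved them)
    i_max, i_min = int(np.argmax(vw)), int(np.argmin(vw))
    order = [i for i in range(n)]
    order.remove(i_max)
    if i_min in order:
        order.remove(i_min)
    order = [i_max] + order + [i_min]
    df = pd.DataFrame(
        {"HT_m": ht[order], "DBH_cm": dbh[order], "VW_m3": vw[order]},
        index=pd.Index(_sample_ids(n), name="sample"),
    )
    return df


def _vw_weight(phen: pd.DataFrame, power: float) -> tuple[np.ndarray, np.ndarray]:
    vw = phen["VW_m3"].to_numpy(float)
    vnorm = (vw - vw.min()) / (vw.max() - vw.min())
    return vnorm**power, vnorm


def _plant_ids(rng: np.random.Generator, config: SimConfig) -> PlantedTruth:
    """Choose planted ids and their per-class roles."""
    sizes = config.class_sizes()
    universe = {
        cls: [f"{cls}_{i + 1:04d}" for i in range(n)] for cls, n in sizes.items()
    }
    k = config.n_planted_triples
    need = {
        "miRNA": k + config.n_extra_de,
        "lncRNA": k + config.n_extra_de,
        "circRNA": k + config.n_extra_de,
        "mRNA": 2 * k + 2 * config.hub_extra_targets + config.n_extra_de
        + config.n_trait_genes,
    }
    for cls, n_needed in need.items():
        if n_needed > sizes[cls]:
            raise ValueError(
                f"planted {cls} count {n_needed} exceeds class size {sizes[cls]}"
            )
    picks = {
        cls: [str(x) for x in rng.choice(universe[cls], size=need[cls],
                                         replace=False)]
        for cls in need
    }
    mi = picks["miRNA"][:k]
    lnc = picks["lncRNA"][:k]
    circ = picks["circRNA"][:k]
    m_iter = iter(picks["mRNA"])
    triples: list[Triple] = []
    for i in range(k):
        triples.append(Triple(lnc[i], "lncRNA", mi[i], next(m_iter)))
        triples.append(Triple(circ[i], "circRNA", mi[i], next(m_iter)))
    hub = mi[0] if k else ""
    hub_extra = [next(m_iter) for _ in range(2 * config.hub_extra_targets)] if k else []
    extra_m = [next(m_iter) for _ in range(config.n_extra_de)]
    trait_genes = [next(m_iter) for _ in range(config.n_trait_genes)]
    elevated = {
        "lncRNA": lnc + picks["lncRNA"][k:],
        "circRNA": circ + picks["circRNA"][k:],
        "mRNA": [t.mrna_id for t in triples] + hub_extra + extra_m,
        "miRNA": [],
    }
    suppressed = {
        "mRNA": [],
        "lncRNA": [],
        "circRNA": [],
        "miRNA": mi + picks["miRNA"][k:],
    }
    truth = PlantedTruth(
        elevated=elevated,
        suppressed=suppressed,
        triples=triples,
        hub_mirna=hub,
        hub_extra_mrnas=hub_extra,
        trait_gene_ids=trait_genes,
        universe=universe,
    )
    return truth


_LENGTH_PARAMS = {  # (mean, sd, minimum) of transcript lengths in bp
    "mRNA": (1500.0, 300.0, 300),
    "lncRNA": (800.0, 200.0, 250),
    "circRNA": (500.0, 100.0, 150),
    "miRNA": (21.0, 0.0, 21),
}


def generate_expression(
    config: SimConfig, phen: pd.DataFrame
) -> tuple[ExpressionBundle, PlantedTruth]:
    """Four expression matrices (normalized + integer counts) with planted DE
    structure and the ground truth describing it."""
    if list(phen.index) != _sample_ids(config.n_samples):
        raise ValueError("phenotypes were generated for a different sample set")
    rng = config.rng(_STREAM_EXPR)
    truth = _plant_ids(rng, config)
    w, vnorm = _vw_weight(phen, config.gradient_power)
    samples = list(phen.index)

    normalized: dict[str, ExpressionMatrix] = {}
    counts: dict[str, ExpressionMatrix] = {}
    lengths: dict[str, pd.Series] = {}
    for cls, ids in truth.universe.items():
        n_rna = len(ids)
        mean_len, sd_len, min_len = _LENGTH_PARAMS[cls]
        length = np.maximum(
            rng.normal(mean_len, sd_len, n_rna), min_len
        ).round().astype(int) if sd_len else np.full(n_rna, int(mean_len))
        base = 2.0 ** rng.normal(7.0, 1.5, n_rna)

        sign = np.zeros(n_rna)
        idx = {rid: i for i, rid in enumerate(ids)}
        # planted regulators are well-expressed (the emulated study displays
        # its key RNAs at FPKM/TPM > 5): floor their baseline mean counts
        planted_all = truth.de_ids(cls)
        if cls == "mRNA":
            planted_all = planted_all | set(truth.trait_gene_ids)
        for rid in planted_all:
            base[idx[rid]] = max(base[idx[rid]], 2.0**8)
        for rid in truth.elevated[cls]:
            sign[idx[rid]] = 1.0
        for rid in truth.suppressed[cls]:
            sign[idx[rid]] = -1.0
        mean = base[:, None] * 2.0 ** (
            config.effect_log2fc * sign[:, None] * w[None, :]
        )
        if cls == "mRNA":
            for rid in truth.trait_gene_ids:
                mean[idx[rid]] = base[idx[rid]] * (0.25 + 1.75 * vnorm)
        noisy = mean * 2.0 ** rng.normal(0.0, config.noise_sd, mean.shape)

        libfac = 1.0 + rng.uniform(-0.1, 0.1, config.n_samples)
        mu = noisy * libfac[None, :]
        if config.dispersion > 0:
            r = 1.0 / config.dispersion
            p = r / (r + mu)
            cnt = rng.negative_binomial(r, p)
        else:
            cnt = rng.poisson(mu)
        cnt_df = pd.DataFrame(cnt, index=pd.Index(ids, name="rna_id"),
                              columns=samples)

        colsum = cnt_df.sum(axis=0).to_numpy(float)
        unit = cio.UNIT_FOR_CLASS[cls]
        if unit == "FPKM":
            norm = cnt / (colsum[None, :] / 1e6) / (length[:, None] / 1e3)
        else:  # TPM for the small-RNA / back-splice libraries
            norm = cnt / colsum[None, :] * 1e6
        norm_df = pd.DataFrame(norm, index=pd.Index(ids, name="rna_id"),
                               columns=samples)

        counts[cls] = ExpressionMatrix(cnt_df, rna_class=cls, unit="count")
        normalized[cls] = ExpressionMatrix(norm_df, rna_class=cls, unit=unit)
        lengths[cls] = pd.Series(length, index=ids, name="length_bp")

    return ExpressionBundle(normalized, counts, lengths), truth


def generate_targets(truth: PlantedTruth, config: SimConfig) -> list[TargetPair]:
    """miRNA->ncRNA and miRNA->mRNA pairs covering every planted triple plus
    decoy pairs among non-DE RNAs."""
    rng = config.rng(_STREAM_TARGETS)
    pairs: list[TargetPair] = []
    seen: set[tuple[str, str]] = set()

    def add(mi: str, target: str, cls: str, score: float) -> None:
        if (mi, target) not in seen:
            seen.add((mi, target))
            pairs.append(TargetPair(mi, target, cls, round(score, 3)))

    for t in truth.triples:
        add(t.mirna_id, t.ncrna_id, t.ncrna_class, rng.uniform(0.0, 2.0))
        add(t.mirna_id, t.mrna_id, "mRNA", rng.uniform(0.0, 2.0))
    for m in truth.hub_extra_mrnas:
        add(truth.hub_mirna, m, "mRNA", rng.uniform(0.0, 2.0))

    pools = {
        cls: [i for i in truth.universe[cls]
              if i not in truth.de_ids(cls) and i not in truth.trait_gene_ids]
        for cls in ("mRNA", "lncRNA", "circRNA")
    }
    decoy_mirnas = [
        i for i in truth.universe["miRNA"] if i not in truth.de_ids("miRNA")
    ]
    target_classes = ("mRNA", "lncRNA", "circRNA")
    n_added = 0
    guard = 0
    while n_added < config.n_decoy_pairs and decoy_mirnas:
        guard += 1
        if guard > 50 * (config.n_decoy_pairs + 1):
            break
        cls = target_classes[int(rng.integers(len(target_classes)))]
        if not pools[cls]:
            continue
        mi = decoy_mirnas[int(rng.integers(len(decoy_mirnas)))]
        tg = pools[cls][int(rng.integers(len(pools[cls])))]
        if (mi, tg) in seen:
            continue
        add(mi, tg, cls, rng.uniform(2.0, 4.0))
        n_added += 1
    return pairs


def generate_snps(config: SimConfig) -> list[SnpRecord]:
    """Biallelic SNPs with per-sample diploid genotypes.

    Substitution types are drawn so the expected transition fraction is
    ``ts_tv_target / (1 + ts_tv_target)``; minor allele counts realize MAFs in
    ``maf_range`` except for a ``maf_below_frac`` fraction planted below the
    0.1 filter boundary.
    """
    if config.n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = config.rng(_STREAM_SNPS)
    n_alleles = 2 * config.n_samples
    p_ts = config.ts_tv_target / (1.0 + config.ts_tv_target)
    transitions = (("C", "T"), ("A", "G"))
    transversions = (("A", "T"), ("A", "C"), ("G", "T"), ("G", "C"))

    pos = np.cumsum(rng.integers(50, 300, size=config.n_sites))
    records: list[SnpRecord] = []
    for i in range(config.n_sites):
        if rng.random() < p_ts:
            pair = transitions[int(rng.integers(2))]
        else:
            pair = transversions[int(rng.integers(4))]
        ref, alt = pair if rng.random() < 0.5 else pair[::-1]
        if rng.random() < config.maf_below_frac:
            minor = 1  # MAF 1/2n, below the 0.1 boundary for n >= 6
        else:
            u = rng.uniform(*config.maf_range)
            minor = int(np.clip(round(u * n_alleles), 1, n_alleles // 2))
        slots = rng.choice(n_alleles, size=minor, replace=False)
        alleles = np.zeros(n_alleles, dtype=int)
        alleles[slots] = 1
        gts = alleles.reshape(config.n_samples, 2)
        records.append(SnpRecord("chr1", int(pos[i]), ref, alt, gts))
    return records


def generate_qpcr(
    truth: PlantedTruth, config: SimConfig, phen: pd.DataFrame
) -> pd.DataFrame:
    """Ct table: reference genes constant across samples up to replicate
    noise; planted trait genes' Cts decrease with expression (one cycle per
    doubling)."""
    rng = config.rng(_STREAM_QPCR)
    _, vnorm = _vw_weight(phen, config.gradient_power)
    samples = list(phen.index)
    rows = []
    for gene in REFERENCE_GENES:
        base = rng.uniform(18.0, 24.0)
        for s in samples:
            for rep in range(1, config.n_qpcr_replicates + 1):
                ct = base + rng.normal(0.0, config.ct_noise_sd)
                rows.append((gene, s, rep, ct, True))
    for gene in truth.trait_gene_ids:
        base = rng.uniform(22.0, 28.0)
        relexp = 0.25 + 1.75 * vnorm
        for s, e in zip(samples, relexp):
            for rep in range(1, config.n_qpcr_replicates + 1):
                ct = base - np.log2(e) + rng.normal(0.0, config.ct_noise_sd)
                rows.append((gene, s, rep, ct, False))
    return pd.DataFrame(
        rows, columns=["gene", "sample", "replicate", "Ct", "is_reference"]
    )


def generate_lnc_annotation(
    lnc_matrix: ExpressionMatrix,
    truth: PlantedTruth,
    config: SimConfig,
    fail_frac: float = 0.2,
) -> tuple[list[TranscriptRecord], list[GeneAnnotation]]:
    """Transcript records and gene annotations exercising the lncRNA filter.

    Planted lncRNAs always satisfy all three rules; a ``fail_frac`` fraction
    of the remaining transcripts is assigned one violation each (low FPKM,
    short, single exon, or within the 1-kb flank of a gene).
    """
    rng = config.rng(_STREAM_LNC_ANNOT)
    genes = [
        GeneAnnotation(f"gene_{i + 1}", "chr1", 1_000_000 * (i + 1),
                       1_000_000 * (i + 1) + 5_000, "+")
        for i in range(5)
    ]
    mean_fpkm = lnc_matrix.values.mean(axis=1)
    planted = truth.de_ids("lncRNA")
    ids = list(lnc_matrix.rna_ids)
    decoys = [i for i in ids if i not in planted]
    n_fail = int(round(fail_frac * len(decoys)))
    fail_ids = [str(x) for x in rng.choice(decoys, size=n_fail, replace=False)] \
        if n_fail else []
    fail_mode = {rid: int(rng.integers(4)) for rid in fail_ids}

    transcripts = []
    cursor = 10_000_000
    for rid in ids:
        length = int(rng.integers(400, 2000))
        exons = int(rng.integers(2, 5))
        fpkm = float(max(mean_fpkm[rid], 0.5))
        start = cursor
        mode = fail_mode.get(rid)
        if mode == 0:
            fpkm = float(rng.uniform(0.0, 0.49))
        elif mode == 1:
            length = int(rng.integers(50, 199))
        elif mode == 2:
            exons = 1
        elif mode == 3:
            g = genes[int(rng.integers(len(genes)))]
            start = g.end + int(rng.integers(0, 999))
        span = max(length + (exons - 1) * 100, length)
        transcripts.append(
            TranscriptRecord(rid, "chr1", start, start + span - 1, "+",
                             exons, length, fpkm)
        )
        cursor += 50_000
    return transcripts, genes


def simulate_all(config: SimConfig, outdir) -> dict:
    """Run every generator and write all inputs under ``outdir``.

    Returns a manifest of paths and record counts.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    phen = generate_phenotypes(config)
    bundle, truth = generate_expression(config, phen)
    targets = generate_targets(truth, config)
    snps = generate_snps(config)
    qpcr = generate_qpcr(truth, config, phen)
    transcripts, genes = generate_lnc_annotation(
        bundle.normalized["lncRNA"], truth, config
    )

    paths: dict[str, str] = {}

    def save(key: str, name: str) -> Path:
        p = out / name
        paths[key] = str(p)
        return p

    cio.write_phenotypes(phen, save("phenotypes", "phenotypes.tsv"))
    for cls in truth.universe:
        unit = cio.UNIT_FOR_CLASS[cls].lower()
        cio.write_expression(
            bundle.normalized[cls], save(f"{cls}_norm", f"{cls}_{unit}.tsv")
        )
        cio.write_expression(
            bundle.counts[cls], save(f"{cls}_counts", f"{cls}_counts.tsv")
        )
    cio.write_targets(targets, save("targets", "targets.tsv"))
    cio.write_vcf(snps, list(phen.index), save("snps", "snps.vcf"))
    cio.write_qpcr(qpcr, save("qpcr", "qpcr.tsv"))
    cio.write_gtf(transcripts, genes, save("lnc_gtf", "lncrna_candidates.gtf"))

    return {
        "paths": paths,
        "n_samples": config.n_samples,
        "n_rnas": {cls: len(ids) for cls, ids in truth.universe.items()},
        "n_targets": len(targets),
        "n_snps": len(snps),
        "truth": {
            "elevated": truth.elevated,
            "suppressed": truth.suppressed,
            "triples": [dataclasses.asdict(t) for t in truth.triples],
            "hub_mirna": truth.hub_mirna,
            "hub_extra_mrnas": truth.hub_extra_mrnas,
            "trait_gene_ids": truth.trait_gene_ids,
        },
    }
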