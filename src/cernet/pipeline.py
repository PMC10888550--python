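"""End-to-end orchestration: simulate (or ingest) -> lncRNA filter -> nine-pair
DE per reference -> consensus -> tripartite networks (both ncRNA kinds, both
references) -> key-miRNA intersection -> correlation screens -> SNP stats ->
qPCR validation, with a JSON run manifest.

Both extreme individuals (highest- and lowest-VW) are processed as reference
samples by default.  Stage artifacts are plain TSV/GraphML/JSON files so each
stage is independently inspectable, and the manifest contains no timestamps:
two runs with the same seed and config produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .assoc import expression_correlation, phenotype_correlation
from .diffexpr import DeParams, call_de
from .lncfilter import FilterParams, filter_lncrna_candidates
from .network import (
    RegulatoryNetwork,
    assemble_network,
    build_comparisons,
    consensus_filter,
    intersect_key_mirnas,
    key_mirnas,
    merge_consensus,
    network_summary,
)
from .qpcr import relative_expression, validation_correlation
from .simulate import (
    REFERENCE_GENES,
    SimConfig,
    generate_expression,
    generate_lnc_annotation,
    generate_phenotypes,
    generate_qpcr,
    generate_snps,
    generate_targets,
)
from .snpstats import maf_filter, tstv_table

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


@dataclass
class PipelineConfig:
    """Full pipeline configuration (simulation world + analysis settings)."""

    sim: SimConfig = field(default_factory=SimConfig)
    de: DeParams | None = None  # default: DeParams with the sim dispersion
    min_support: int = 6
    require_anticorrelation: bool = True  # matches the simulated ceRNA world
    support_mode: str = "min"
    key_mirna_min_degree: int = 1
    expr_r_min: float = 0.8
    expr_p_max: float = 0.01
    trait: str = "VW"
    trait_r_min: float = 0.6
    trait_p_max: float = 0.05
    min_maf: float = 0.1
    lnc_filter: FilterParams = field(default_factory=FilterParams)

    def de_params(self) -> DeParams:
        return self.de or DeParams(dispersion=self.sim.dispersion)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, cause: BaseException, manifest: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute all stages for both reference samples and both network kinds.

    Returns the run manifest (also written to ``outdir/manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.sim.seed,
        "config": _jsonable(config),
        "stages": {},
        "artifacts": {},
    }
    stage = "simulate"
    try:
        from .simulate import simulate_all

        sim_dir = out / "inputs"
        sim_manifest = simulate_all(config.sim, sim_dir)
        manifest["stages"]["simulate"] = {
            k: v for k, v in sim_manifest.items() if k != "paths"
        }
        manifest["artifacts"].update(sim_manifest["paths"])

        phen = generate_phenotypes(config.sim)
        bundle, truth = generate_expression(config.sim, phen)
        targets = generate_targets(truth, config.sim)
        samples = list(phen.index)
        ref_high = phen["VW_m3"].idxmax()
        ref_low = phen["VW_m3"].idxmin()
        references = [ref_high, ref_low]
        manifest["samples"] = samples
        manifest["references"] = references

        stage = "lncfilter"
        transcripts, genes = generate_lnc_annotation(
            bundle.normalized["lncRNA"], truth, config.sim
        )
        retained, report = filter_lncrna_candidates(
            transcripts, genes, config.lnc_filter
        )
        retained_ids = [t.transcript_id for t in retained]
        manifest["stages"]["lncfilter"] = report.to_dict()
        (out / "lncrna_retained.txt").write_text("\n".join(retained_ids) + "\n")
        manifest["artifacts"]["lncrna_retained"] = str(out / "lncrna_retained.txt")
        lnc_counts = bundle.counts["lncRNA"].values.loc[retained_ids]
        class_counts = {
            "mRNA": bundle.counts["mRNA"].values,
            "lncRNA": lnc_counts,
            "circRNA": bundle.counts["circRNA"].values,
            "miRNA": bundle.counts["miRNA"].values,
        }

        stage = "diffexpr"
        de_params = config.de_params()
        results: dict[str, dict[str, list]] = {}
        de_counts: dict[str, dict[str, int]] = {}
        for ref in references:
            results[ref] = {}
            de_counts[ref] = {}
            for cls, counts in class_counts.items():
                pairs = build_comparisons(samples, ref)
                res = [
                    call_de(counts, r, t, de_params, rna_class=cls)
                    for r, t in pairs
                ]
                results[ref][cls] = res
                de_counts[ref][cls] = int(
                    sum((r.table["status"] != "ns").sum() for r in res)
                )
        manifest["stages"]["diffexpr"] = {
            "params": _jsonable(de_params),
            "n_de_calls": de_counts,
        }

        stage = "consensus"
        consensus = {}
        cons_sizes: dict[str, dict[str, int]] = {}
        for ref in references:
            per_class = {
                cls: consensus_filter(res, config.min_support)
                for cls, res in results[ref].items()
            }
            merged = merge_consensus(per_class.values())
            consensus[ref] = merged
            cons_sizes[ref] = {
                cls: int(len(cs.entries)) for cls, cs in per_class.items()
            }
            path = out / f"consensus_{ref}.tsv"
            merged.entries.to_csv(path, sep="\t", index=False)
            manifest["artifacts"][f"consensus_{ref}"] = str(path)
        manifest["stages"]["consensus"] = {
            "min_support": config.min_support,
            "sizes": cons_sizes,
        }

        stage = "network"
        networks: dict[str, dict[str, RegulatoryNetwork]] = {}
        net_stage: dict[str, dict] = {}
        for ref in references:
            networks[ref] = {}
            net_stage[ref] = {}
            for kind in ("lncRNA", "circRNA"):
                net = assemble_network(
                    consensus[ref],
                    targets,
                    kind=kind,
                    require_anticorrelation=config.require_anticorrelation,
                    support_mode=config.support_mode,
                    results_by_class=results[ref],
                )
                networks[ref][kind] = net
                tsv = out / f"network_{kind}_{ref}.tsv"
                gml = out / f"network_{kind}_{ref}.graphml"
                cio.write_network(net, tsv, "tsv")
                cio.write_network(net, gml, "graphml")
                manifest["artifacts"][f"network_{kind}_{ref}"] = str(tsv)
                manifest["artifacts"][f"network_{kind}_{ref}_graphml"] = str(gml)
                net_stage[ref][kind] = network_summary(net)
        manifest["stages"]["network"] = net_stage

        stage = "key_mirnas"
        keys: dict[str, dict[str, list[str]]] = {}
        intersections: dict[str, list[str]] = {}
        for ref in references:
            keys[ref] = {
                kind: key_mirnas(
                    networks[ref][kind], min_degree=config.key_mirna_min_degree
                )["mirna_id"].tolist()
                for kind in ("lncRNA", "circRNA")
            }
            intersections[ref] = intersect_key_mirnas(
                keys[ref]["lncRNA"], keys[ref]["circRNA"]
            )
        manifest["stages"]["key_mirnas"] = {
            "per_network": keys,
            "intersection": intersections,
        }

        stage = "correlation"
        lnc_norm = bundle.normalized["lncRNA"].values.loc[retained_ids]
        mi_norm = bundle.normalized["miRNA"].values
        expr_hits = expression_correlation(
            lnc_norm, mi_norm, config.expr_r_min, config.expr_p_max
        )
        trait_hits = phenotype_correlation(
            bundle.normalized["mRNA"],
            phen,
            config.trait,
            config.trait_r_min,
            config.trait_p_max,
        )
        corr_path = out / "lncrna_mirna_correlations.tsv"
        pd.DataFrame([dataclasses.asdict(h) for h in expr_hits]).to_csv(
            corr_path, sep="\t", index=False
        )
        manifest["artifacts"]["lncrna_mirna_correlations"] = str(corr_path)
        manifest["stages"]["correlation"] = {
            "lncRNA_miRNA_hits": len(expr_hits),
            "trait": config.trait,
            "trait_positive": len(trait_hits["positive"]),
            "trait_negative": len(trait_hits["negative"]),
        }

        stage = "snpstats"
        snps, vcf_report = cio.read_vcf(
            manifest["artifacts"]["snps"], config.sim.n_samples
        )
        kept = maf_filter(snps, config.min_maf)
        table = tstv_table(kept)
        manifest["stages"]["snpstats"] = {
            "n_input": vcf_report.n_kept,
            "n_after_maf": len(kept),
            "min_maf": config.min_maf,
            "tstv": table.to_dict(),
        }

        stage = "qpcr"
        qpcr_table = generate_qpcr(truth, config.sim, phen)
        calibrator = ref_low  # lowest-VW individual as calibrator
        relexp = pd.DataFrame(
            {
                gene: relative_expression(
                    qpcr_table, gene, list(REFERENCE_GENES), calibrator
                )
                for gene in truth.trait_gene_ids
            }
        )
        val, val_errors = validation_correlation(relexp, phen, config.trait)
        manifest["stages"]["qpcr"] = {
            "calibrator": calibrator,
            "genes": truth.trait_gene_ids,
            "significant": [
                v.id_a for v in val if v.p < config.trait_p_max and v.r > 0
            ],
            "errors": val_errors,
        }
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc, manifest) from exc

    manifest = _jsonable(manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
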