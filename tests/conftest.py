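"""Shared fixtures: a small simulated dataset and a reference-anchored
analysis chain reused across test modules."""

from __future__ import annotations

import pytest

from cernet.diffexpr import DeParams, call_de
from cernet.network import (
    assemble_network,
    build_comparisons,
    consensus_filter,
    merge_consensus,
)
from cernet.simulate import (
    SimConfig,
    generate_expression,
    generate_phenotypes,
    generate_targets,
)

#: compact world used by most integration-style tests (keeps the exact-test
#: enumeration fast without changing the structure of the default world)
SMALL = dict(
    n_mrna=120,
    n_lncrna=80,
    n_circrna=40,
    n_mirna=30,
    n_planted_triples=3,
    n_extra_de=5,
    hub_extra_targets=2,
    n_trait_genes=4,
    n_sites=600,
    n_decoy_pairs=25,
)

#: the spec'd low-noise recovery regime: strong planted effect, tight counts
LOW_NOISE = dict(dispersion=0.02, noise_sd=0.05, effect_log2fc=3.0)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def phenotypes(small_config):
    return generate_phenotypes(small_config)


@pytest.fixture(scope="session")
def dataset(small_config, phenotypes):
    bundle, truth = generate_expression(small_config, phenotypes)
    targets = generate_targets(truth, small_config)
    return bundle, truth, targets


def run_reference_analysis(config: SimConfig, reference: str = "SS1",
                           min_support: int = 6,
                           require_anticorrelation: bool = True):
    """Generator -> nine-pair DE -> consensus -> both network kinds."""
    phen = generate_phenotypes(config)
    bundle, truth = generate_expression(config, phen)
    targets = generate_targets(truth, config)
    samples = list(phen.index)
    params = DeParams(dispersion=config.dispersion)
    results = {
        cls: [
            call_de(bundle.counts[cls].values, r, t, params, rna_class=cls)
            for r, t in build_comparisons(samples, reference)
        ]
        for cls in ("mRNA", "lncRNA", "circRNA", "miRNA")
    }
    consensus = merge_consensus(
        [consensus_filter(v, min_support) for v in results.values()]
    )
    nets = {
        kind: assemble_network(
            consensus, targets, kind,
            require_anticorrelation=require_anticorrelation,
        )
        for kind in ("lncRNA", "circRNA")
    }
    return phen, bundle, truth, targets, results, consensus, nets
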