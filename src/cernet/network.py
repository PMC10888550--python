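"""Reference-anchored consensus filtering and tripartite ceRNA network assembly.

The procedure anchors all pairwise comparisons on a reference individual (the
tree with the highest or lowest wood volume): with 10 individuals this yields
nine (reference, test) pairs per RNA class.  An RNA enters the consensus set
for a direction when it is called DE in that direction in at least
``min_support`` of the pairs (default 6 of 9).  Networks are then assembled
from predicted miRNA-target pairs: an edge joins an ncRNA (lncRNA or circRNA)
to a miRNA, or a miRNA to an mRNA, when both endpoints are in the consensus
set.  By default both endpoints must share a DE direction (as in the source
procedure); the ``require_anticorrelation`` mode instead demands opposite
directions between the miRNA and its targets, the behaviour expected of a
competing-endogenous-RNA relationship.

Key miRNAs are the mediators with the largest number of distinct consensus
neighbours across both adjacent layers; miRNAs shared between the lncRNA- and
circRNA-anchored networks are the core candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .diffexpr import ComparisonResult
from .io import TargetPair

__all__ = [
    "ConsensusSet",
    "RegulatoryNetwork",
    "build_comparisons",
    "consensus_filter",
    "assemble_network",
    "network_summary",
    "connection_total",
    "key_mirnas",
    "intersect_key_mirnas",
]

_CONSENSUS_COLS = ["rna_id", "rna_class", "direction", "support"]
_EDGE_COLS = ["source", "source_class", "target", "target_class",
              "direction", "support"]


@dataclass
class ConsensusSet:
    """RNAs DE in the same direction in >= min_support pairs vs one reference."""

    reference: str
    min_support: int
    n_pairs: int
    entries: pd.DataFrame  # columns: rna_id, rna_class, direction, support

    def ids(self, rna_class: str | None = None, direction: str | None = None):
        df = self.entries
        if rna_class is not None:
            df = df[df["rna_class"] == rna_class]
        if direction is not None:
            df = df[df["direction"] == direction]
        return set(df["rna_id"])


@dataclass
class RegulatoryNetwork:
    """Directional tripartite network (ncRNA <-> miRNA <-> mRNA edges)."""

    kind: str  # "lncRNA" or "circRNA" (the ncRNA layer)
    reference: str
    edges: pd.DataFrame  # columns: _EDGE_COLS


def build_comparisons(
    sample_ids: Sequence[str], reference_sample: str
) -> list[tuple[str, str]]:
    """One (reference, test) pair per non-reference sample, in input order."""
    if reference_sample not in sample_ids:
        raise KeyError(f"reference {reference_sample!r} not among samples")
    if len(sample_ids) < 2:
        raise ValueError("need at least two samples")
    return [(reference_sample, s) for s in sample_ids if s != reference_sample]


def consensus_filter(
    results: Iterable[ComparisonResult], min_support: int = 6
) -> ConsensusSet:
    """Collect RNAs DE in the same direction in >= min_support comparisons."""
    results = list(results)
    if not results:
        raise ValueError("no comparison results given")
    refs = {r.reference for r in results}
    if len(refs) > 1:
        raise ValueError(f"mixed reference samples: {sorted(refs)}")
    classes = {r.rna_class for r in results}
    if len(classes) > 1:
        raise ValueError(f"mixed RNA classes: {sorted(classes)}")
    reference = results[0].reference
    rna_class = results[0].rna_class

    support: dict[tuple[str, str], int] = {}
    for res in results:
        de = res.table[res.table["status"] != "ns"]
        for rna_id, direction in zip(de.index, de["status"]):
            support[(rna_id, direction)] = support.get((rna_id, direction), 0) + 1

    rows = [
        (rna_id, rna_class, direction, n)
        for (rna_id, direction), n in support.items()
        if n >= min_support
    ]
    entries = pd.DataFrame(rows, columns=_CONSENSUS_COLS)
    entries = entries.sort_values(["direction", "rna_id"], ignore_index=True)
    return ConsensusSet(reference, min_support, len(results), entries)


def merge_consensus(sets: Iterable[ConsensusSet]) -> ConsensusSet:
    """Concatenate per-class consensus sets sharing one reference."""
    sets = list(sets)
    refs = {s.reference for s in sets}
    if len(refs) != 1:
        raise ValueError("consensus sets must share a reference")
    entries = pd.concat([s.entries for s in sets], ignore_index=True)
    return ConsensusSet(
        sets[0].reference,
        min(s.min_support for s in sets),
        max(s.n_pairs for s in sets),
        entries,
    )


def _joint_support(
    results_by_class: dict[str, list[ComparisonResult]],
    id_a: str, class_a: str, dir_a: str,
    id_b: str, class_b: str, dir_b: str,
) -> int:
    """Number of comparison pairs where both endpoints are simultaneously DE."""
    res_a = {(r.reference, r.test): r for r in results_by_class.get(class_a, [])}
    res_b = {(r.reference, r.test): r for r in results_by_class.get(class_b, [])}
    n = 0
    for key, ra in res_a.items():
        rb = res_b.get(key)
        if rb is None:
            continue
        sa = ra.table["status"].get(id_a, "ns")
        sb = rb.table["status"].get(id_b, "ns")
        if sa == dir_a and sb == dir_b:
            n += 1
    return n


def assemble_network(
    consensus: ConsensusSet,
    targets: Iterable[TargetPair],
    kind: str = "lncRNA",
    require_anticorrelation: bool = False,
    support_mode: str = "min",
    results_by_class: dict[str, list[ComparisonResult]] | None = None,
) -> RegulatoryNetwork:
    """Build the directional tripartite network from consensus RNAs and
    predicted miRNA-target pairs.

    Parameters
    ----------
    kind
        ncRNA layer: "lncRNA" or "circRNA".
    require_anticorrelation
        If False (default, mirroring the source procedure) an edge requires
        both endpoints DE in the same direction, which becomes the edge
        direction.  If True the miRNA must be DE opposite to its target, and
        the edge carries the direction of the non-miRNA endpoint.
    support_mode
        "min": edge support = min of the two endpoint supports (default).
        "joint": count of pairs where both endpoints are simultaneously DE
        (requires ``results_by_class``).
    """
    if kind not in ("lncRNA", "circRNA"):
        raise ValueError("kind must be 'lncRNA' or 'circRNA'")
    if support_mode not in ("min", "joint"):
        raise ValueError("support_mode must be 'min' or 'joint'")
    if support_mode == "joint" and results_by_class is None:
        raise ValueError("support_mode='joint' needs results_by_class")

    # an id may appear once per direction; index all its entries
    by_id_class: dict[tuple[str, str], list[tuple[str, int]]] = {}
    for row in consensus.entries.itertuples(index=False):
        by_id_class.setdefault((row.rna_id, row.rna_class), []).append(
            (row.direction, int(row.support))
        )

    opposite = {"up": "down", "down": "up"}
    rows = []
    seen = set()
    for pair in targets:
        if pair.target_class not in (kind, "mRNA"):
            continue
        mi_entries = by_id_class.get((pair.mirna_id, "miRNA"), [])
        tg_entries = by_id_class.get((pair.target_id, pair.target_class), [])
        for mi_dir, mi_sup in mi_entries:
            for tg_dir, tg_sup in tg_entries:
                wanted = opposite[mi_dir] if require_anticorrelation else mi_dir
                if tg_dir != wanted:
                    continue
                edge_dir = tg_dir if require_anticorrelation else mi_dir
                if pair.target_class == kind:  # ncRNA -- miRNA edge
                    src, src_cls = pair.target_id, pair.target_class
                    dst, dst_cls = pair.mirna_id, "miRNA"
                else:  # miRNA -- mRNA edge
                    src, src_cls = pair.mirna_id, "miRNA"
                    dst, dst_cls = pair.target_id, "mRNA"
                key = (src, dst, edge_dir)
                if key in seen:
                    continue
                seen.add(key)
                if support_mode == "min":
                    sup = min(mi_sup, tg_sup)
                else:
                    sup = _joint_support(
                        results_by_class,
                        pair.mirna_id, "miRNA", mi_dir,
                        pair.target_id, pair.target_class, tg_dir,
                    )
                if sup < 1:
                    continue
                rows.append((src, src_cls, dst, dst_cls, edge_dir, sup))

    edges = pd.DataFrame(rows, columns=_EDGE_COLS)
    edges = edges.sort_values(_EDGE_COLS[:3], ignore_index=True)
    return RegulatoryNetwork(kind, consensus.reference, edges)


def connection_total(class_counts: Iterable[int]) -> int:
    """Total connections as the sum over the (layer-pair x direction) classes."""
    return int(sum(int(c) for c in class_counts))


def network_summary(net: RegulatoryNetwork) -> dict:
    """Connection counts per (layer pair, direction), their total, and the
    number of distinct nodes per RNA class."""
    e = net.edges
    nc = net.kind

    def count(src_cls: str, dst_cls: str, direction: str) -> int:
        return int(
            (
                (e["source_class"] == src_cls)
                & (e["target_class"] == dst_cls)
                & (e["direction"] == direction)
            ).sum()
        )

    per_class = {
        f"{nc}-miRNA_up": count(nc, "miRNA", "up"),
        f"miRNA-mRNA_up": count("miRNA", "mRNA", "up"),
        f"{nc}-miRNA_down": count(nc, "miRNA", "down"),
        f"miRNA-mRNA_down": count("miRNA", "mRNA", "down"),
    }
    nodes: dict[str, int] = {}
    for cls in (nc, "miRNA", "mRNA"):
        ids = set(e.loc[e["source_class"] == cls, "source"]) | set(
            e.loc[e["target_class"] == cls, "target"]
        )
        nodes[cls] = len(ids)
    return {
        "kind": net.kind,
        "reference": net.reference,
        "connections": per_class,
        "total": connection_total(per_class.values()),
        "nodes": nodes,
    }


def key_mirnas(
    net: RegulatoryNetwork,
    k: int | None = None,
    min_degree: int | None = None,
) -> pd.DataFrame:
    """miRNAs ranked by total degree (distinct neighbours in both layers).

    Ties are broken lexicographically by id.  Returns the top ``k``, or all
    miRNAs with degree >= ``min_degree``; with neither, all ranked miRNAs.
    """
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    neighbours: dict[str, set[str]] = {}
    for row in net.edges.itertuples(index=False):
        if row.source_class == "miRNA":
            neighbours.setdefault(row.source, set()).add(row.target)
        if row.target_class == "miRNA":
            neighbours.setdefault(row.target, set()).add(row.source)
    ranked = sorted(
        ((mi, len(nb)) for mi, nb in neighbours.items()),
        key=lambda t: (-t[1], t[0]),
    )
    df = pd.DataFrame(ranked, columns=["mirna_id", "degree"])
    if min_degree is not None:
        df = df[df["degree"] >= min_degree].reset_index(drop=True)
    if k is not None:
        df = df.head(k).reset_index(drop=True)
    return df


def intersect_key_mirnas(list_a: Iterable[str], list_b: Iterable[str]) -> list[str]:
    """Sorted intersection of two key-miRNA id lists."""
    return sorted(set(list_a) & set(list_b))
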