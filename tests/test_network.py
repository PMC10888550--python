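"""Consensus filtering, network assembly, summaries and key-miRNA ranking."""

from __future__ import annotations

import pandas as pd
import pytest

from cernet.diffexpr import ComparisonResult
from cernet.io import TargetPair
from cernet.network import (
    ConsensusSet,
    assemble_network,
    build_comparisons,
    connection_total,
    consensus_filter,
    intersect_key_mirnas,
    key_mirnas,
    network_summary,
)

SAMPLES = [f"SS{i}" for i in range(1, 11)]


def make_result(reference, test, statuses, rna_class="mRNA"):
    """ComparisonResult with given {rna_id: status}; other fields dummies."""
    table = pd.DataFrame(
        {
            "count_ref": 10,
            "count_test": 10,
            "log2fc": [2.0 if s == "up" else -2.0 if s == "down" else 0.0
                       for s in statuses.values()],
            "p": [0.001 if s != "ns" else 0.9 for s in statuses.values()],
            "q": 0.01,
            "status": list(statuses.values()),
        },
        index=pd.Index(list(statuses), name="rna_id"),
    )
    return ComparisonResult(reference, test, rna_class, table)


def make_consensus(rows, reference="SS1", min_support=6):
    entries = pd.DataFrame(
        rows, columns=["rna_id", "rna_class", "direction", "support"]
    )
    return ConsensusSet(reference, min_support, 9, entries)


class TestBuildComparisons:
    def test_ten_samples_give_nine_pairs(self):
        pairs = build_comparisons(SAMPLES, "SS1")
        assert len(pairs) == 9
        assert all(r == "SS1" for r, _ in pairs)
        assert [t for _, t in pairs] == SAMPLES[1:]

    def test_two_samples_one_pair(self):
        assert build_comparisons(["a", "b"], "b") == [("b", "a")]

    def test_missing_reference(self):
        with pytest.raises(KeyError):
            build_comparisons(SAMPLES, "SS99")


class TestConsensusFilter:
    def _results(self, pattern):
        """Nine comparisons vs SS1; pattern maps rna -> list of 9 statuses."""
        out = []
        for i, test in enumerate(SAMPLES[1:]):
            statuses = {rna: states[i] for rna, states in pattern.items()}
            out.append(make_result("SS1", test, statuses))
        return out

    def test_support_counting(self):
        res = self._results(
            {
                "a": ["up"] * 7 + ["ns"] * 2,  # in, support 7
                "b": ["up"] * 5 + ["ns"] * 4,  # out
                "c": ["up"] * 4 + ["down"] * 3 + ["ns"] * 2,  # out both ways
                "d": ["down"] * 9,  # in, support 9
            }
        )
        cs = consensus_filter(res, min_support=6)
        got = {
            (r.rna_id, r.direction): r.support
            for r in cs.entries.itertuples(index=False)
        }
        assert got == {("a", "up"): 7, ("d", "down"): 9}

    def test_min_support_monotonicity(self):
        res = self._results({"a": ["up"] * 6 + ["ns"] * 3, "b": ["up"] * 8 + ["ns"]})
        for lo, hi in [(6, 7), (7, 9)]:
            ids_lo = consensus_filter(res, lo).ids()
            ids_hi = consensus_filter(res, hi).ids()
            assert ids_hi <= ids_lo

    def test_mixed_references_rejected(self):
        res = [
            make_result("SS1", "SS2", {"a": "up"}),
            make_result("SS10", "SS2", {"a": "up"}),
        ]
        with pytest.raises(ValueError, match="mixed"):
            consensus_filter(res)


TARGETS = [
    TargetPair("mi1", "lnc1", "lncRNA"),
    TargetPair("mi1", "g1", "mRNA"),
    TargetPair("mi2", "lnc2", "lncRNA"),
    TargetPair("mi2", "g2", "mRNA"),
]


class TestAssembleNetwork:
    def test_same_direction_rule(self):
        cs = make_consensus(
            [
                ("lnc1", "lncRNA", "up", 7),
                ("mi1", "miRNA", "up", 8),
                ("g1", "mRNA", "up", 6),
                # opposite-direction pair: must produce no edge by default
                ("lnc2", "lncRNA", "down", 9),
                ("mi2", "miRNA", "up", 9),
            ]
        )
        net = assemble_network(cs, TARGETS, "lncRNA")
        edges = {(r.source, r.target, r.direction, r.support)
                 for r in net.edges.itertuples(index=False)}
        assert edges == {("lnc1", "mi1", "up", 7), ("mi1", "g1", "up", 6)}

    def test_anticorrelation_rule_links_opposites(self):
        cs = make_consensus(
            [
                ("lnc1", "lncRNA", "down", 7),
                ("mi1", "miRNA", "up", 8),
                ("g1", "mRNA", "down", 6),
            ]
        )
        assert assemble_network(cs, TARGETS, "lncRNA").edges.empty
        net = assemble_network(cs, TARGETS, "lncRNA", require_anticorrelation=True)
        # edge direction carries the non-miRNA endpoint's direction
        edges = {(r.source, r.target, r.direction)
                 for r in net.edges.itertuples(index=False)}
        assert edges == {("lnc1", "mi1", "down"), ("mi1", "g1", "down")}

    def test_support_is_min_of_endpoints(self):
        cs = make_consensus(
            [("lnc1", "lncRNA", "up", 9), ("mi1", "miRNA", "up", 6)]
        )
        net = assemble_network(cs, TARGETS, "lncRNA")
        assert net.edges["support"].tolist() == [6]

    def test_non_consensus_targets_excluded(self):
        cs = make_consensus([("mi1", "miRNA", "up", 9)])
        assert assemble_network(cs, TARGETS, "lncRNA").edges.empty

    def test_kind_separates_ncrna_layers(self):
        cs = make_consensus(
            [
                ("c1", "circRNA", "up", 7),
                ("mi1", "miRNA", "up", 7),
            ]
        )
        targets = [TargetPair("mi1", "c1", "circRNA")]
        assert assemble_network(cs, targets, "lncRNA").edges.empty
        assert len(assemble_network(cs, targets, "circRNA").edges) == 1


class TestSummary:
    def _net_with_counts(self, n_lm_up, n_mm_up, n_lm_down, n_mm_down):
        rows = []
        for i in range(n_lm_up):
            rows.append((f"l{i}", "lncRNA", f"m{i % 40}", "miRNA", "up", 6))
        for i in range(n_mm_up):
            rows.append((f"m{i % 40}", "miRNA", f"g{i}", "mRNA", "up", 6))
        for i in range(n_lm_down):
            rows.append((f"L{i}", "lncRNA", f"M{i % 10}", "miRNA", "down", 6))
        for i in range(n_mm_down):
            rows.append((f"M{i % 10}", "miRNA", f"G{i}", "mRNA", "down", 6))
        from cernet.network import RegulatoryNetwork

        edges = pd.DataFrame(
            rows, columns=["source", "source_class", "target", "target_class",
                           "direction", "support"],
        )
        return RegulatoryNetwork("lncRNA", "SS1", edges)

    def test_total_is_sum_of_four_classes(self):
        net = self._net_with_counts(12, 9, 4, 3)
        s = network_summary(net)
        assert s["total"] == 28 == sum(s["connections"].values())

    def test_connection_total(self):
        assert connection_total([12, 9, 4, 3]) == 28


class TestKeyMirnas:
    def _toy_net(self):
        from cernet.network import RegulatoryNetwork

        rows = [
            ("l1", "lncRNA", "A", "miRNA", "up", 6),
            ("l2", "lncRNA", "A", "miRNA", "up", 6),
            ("A", "miRNA", "g1", "mRNA", "up", 6),
            ("A", "miRNA", "g2", "mRNA", "up", 6),
            ("A", "miRNA", "g3", "mRNA", "up", 6),
            ("l1", "lncRNA", "B", "miRNA", "up", 6),
            ("B", "miRNA", "g1", "mRNA", "up", 6),
            ("B", "miRNA", "g2", "mRNA", "up", 6),
        ]
        edges = pd.DataFrame(
            rows, columns=["source", "source_class", "target", "target_class",
                           "direction", "support"],
        )
        return RegulatoryNetwork("lncRNA", "SS1", edges)

    def test_degree_ranking(self):
        ranked = key_mirnas(self._toy_net())
        assert ranked["mirna_id"].tolist() == ["A", "B"]
        assert ranked["degree"].tolist() == [5, 3]
        assert key_mirnas(self._toy_net(), k=1)["mirna_id"].tolist() == ["A"]

    def test_lexicographic_tie_break(self):
        from cernet.network import RegulatoryNetwork

        rows = [
            ("l1", "lncRNA", "z", "miRNA", "up", 6),
            ("l1", "lncRNA", "a", "miRNA", "up", 6),
            ("l1", "lncRNA", "m", "miRNA", "up", 6),
        ]
        edges = pd.DataFrame(
            rows, columns=["source", "source_class", "target", "target_class",
                           "direction", "support"],
        )
        net = RegulatoryNetwork("lncRNA", "SS1", edges)
        assert key_mirnas(net)["mirna_id"].tolist() == ["a", "m", "z"]

    def test_min_degree_threshold(self):
        assert key_mirnas(self._toy_net(), min_degree=4)["mirna_id"].tolist() == ["A"]

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            key_mirnas(self._toy_net(), k=0)


class TestIntersect:
    def test_basic_set_behaviour(self):
        assert intersect_key_mirnas(["a", "b"], ["c"]) == []
        assert intersect_key_mirnas(["a", "b"], ["b", "a"]) == ["a", "b"]
        assert intersect_key_mirnas(["x", "y", "z"], ["y", "q", "x"]) == ["x", "y"]
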