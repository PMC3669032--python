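"""GOI subnetwork induction, connection counting and tier assignment."""

from __future__ import annotations

import numpy as np
import pytest

from bihemi.datatypes import GeneAnnotation, InteractionNetwork
from bihemi.diffexpr import FoldChangeRecord
from bihemi.gih import (
    assign_tier,
    build_gih,
    connection_count,
    induce_goi_network,
)
from bihemi.reference_data import GOI_HIERARCHY, GOI_TIER_SIZES, goi_symbols


class TestInduce:
    def test_keeps_only_internal_edges(self):
        net = InteractionNetwork(edges=[("A", "B"), ("B", "D")])
        sub = induce_goi_network(net, {"A", "B", "C"})
        assert sub.edges == {frozenset("AB")}
        assert sub.nodes == {"A", "B", "C"}  # C isolated

    def test_goi_disjoint_from_network_all_isolated(self):
        net = InteractionNetwork(edges=[("X", "Y")])
        sub = induce_goi_network(net, {"A", "B"})
        assert sub.n_edges == 0
        assert sub.nodes == {"A", "B"}

    def test_matches_brute_force_edge_filter_on_seeded_graph(self):
        rng = np.random.default_rng(13)
        nodes = [f"N{i}" for i in range(60)]
        edges = [
            (nodes[i], nodes[j])
            for i, j in rng.integers(0, 60, size=(200, 2))
            if i != j
        ]
        net = InteractionNetwork(nodes=nodes, edges=edges)
        goi = set(rng.choice(nodes, size=25, replace=False))
        sub = induce_goi_network(net, goi)
        oracle = {e for e in net.edges if all(n in goi for n in e)}
        assert sub.edges == oracle

    def test_empty_goi_rejected(self):
        with pytest.raises(ValueError):
            induce_goi_network(InteractionNetwork(), set())


class TestConnectionCount:
    def test_star_center_counts_leaves(self):
        net = InteractionNetwork(edges=[("HUB", f"L{i}") for i in range(15)])
        assert connection_count(net, "HUB") == 15

    def test_isolated_node_zero(self):
        net = InteractionNetwork(nodes=["X"])
        assert connection_count(net, "X") == 0

    def test_duplicate_edges_count_once(self):
        net = InteractionNetwork(edges=[("A", "B"), ("B", "A"), ("A", "B")])
        assert connection_count(net, "A") == 1

    def test_unknown_symbol_rejected(self):
        with pytest.raises(KeyError):
            connection_count(InteractionNetwork(nodes=["A"]), "Z")


class TestAssignTier:
    @pytest.mark.parametrize(
        "count,tier",
        [
            (15, "primary"),
            (11, "primary"),
            (10, "secondary"),
            (7, "secondary"),
            (5, "secondary"),
            (4, "peripheral"),
            (1, "peripheral"),
            (0, "orphan"),
        ],
    )
    def test_boundaries(self, count, tier):
        assert assign_tier(count) == tier

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            assign_tier(-1)

    def test_total_and_monotone(self):
        order = {"orphan": 0, "peripheral": 1, "secondary": 2, "primary": 3}
        ranks = [order[assign_tier(c)] for c in range(0, 30)]
        assert ranks == sorted(ranks)


class TestBuildGih:
    def test_planted_tier_sizes_recovered(self):
        from bihemi.simulate import generate_network

        net, truth = generate_network(seed=99)
        table = build_gih(net, list(truth))
        assert table.tier_totals == {
            "primary": 20,
            "secondary": 34,
            "peripheral": 41,
            "orphan": 19,
        }
        assert table.n_connected == 95
        assert table.n_orphan == 19
        for entry in table.entries:
            assert entry.tier == truth[entry.symbol]

    def test_all_isolated_goi_all_orphan(self):
        net = InteractionNetwork(nodes=["A", "B", "C"])
        table = build_gih(net, ["A", "B", "C"])
        assert all(e.tier == "orphan" for e in table.entries)

    def test_handshake_lemma(self):
        from bihemi.simulate import generate_network

        net, truth = generate_network(seed=4)
        sub = induce_goi_network(net, set(truth))
        total = sum(connection_count(sub, n) for n in sub.nodes)
        assert total == 2 * sub.n_edges

    def test_removing_edge_never_increases_counts(self):
        rng = np.random.default_rng(2)
        nodes = [f"N{i}" for i in range(30)]
        edges = [
            (nodes[i], nodes[j])
            for i, j in rng.integers(0, 30, size=(80, 2))
            if i != j
        ]
        net = InteractionNetwork(nodes=nodes, edges=edges)
        before = {n: connection_count(net, n) for n in net.nodes}
        victim = next(iter(net.edges))
        a, b = tuple(victim)
        net.graph.remove_edge(a, b)
        after = {n: connection_count(net, n) for n in net.nodes}
        assert all(after[n] <= before[n] for n in net.nodes)

    def test_fold_change_cells_follow_changed_flags(self):
        net = InteractionNetwork(edges=[("CEBPB", "X")])
        fc = {
            "CEBPB": FoldChangeRecord(
                "CEBPB", 3.37, 1.2, True, True, True, False
            )
        }
        table = build_gih(net, ["CEBPB"], fold_changes=fc)
        [entry] = table.entries
        assert entry.fc_ipsi == pytest.approx(3.37)
        assert entry.fc_contra is None  # renders "~"

    def test_missing_annotation_yields_unknown_compartment(self, caplog):
        net = InteractionNetwork(edges=[("A", "B")])
        ann = {"A": GeneAnnotation("A", "A", "", "nucleus", "kinase")}
        with caplog.at_level("WARNING"):
            table = build_gih(net, ["A", "B"], annotations=ann)
        by_symbol = {e.symbol: e for e in table.entries}
        assert by_symbol["B"].compartment == "unknown"
        assert "B" in caplog.text

    def test_display_order_tier_then_compartment(self):
        """Entries come out grouped by tier, then compartment rank."""
        from bihemi.datatypes import COMPARTMENT_ORDER
        from bihemi.gih import TIERS
        from bihemi.simulate import generate_network

        net, truth = generate_network(seed=1)
        ann = {
            n: GeneAnnotation(
                n, n, "", COMPARTMENT_ORDER[i % 4], "other"
            )
            for i, n in enumerate(sorted(truth))
        }
        table = build_gih(net, list(truth), annotations=ann)
        keys = [
            (TIERS.index(e.tier), COMPARTMENT_ORDER.index(e.compartment))
            for e in table.entries
        ]
        assert keys == sorted(keys)


class TestPublishedHierarchyFixture:
    def test_tier_sizes_sum_to_114(self):
        assert sum(GOI_TIER_SIZES.values()) == 114
        assert len(goi_symbols()) == 114
        counted = {}
        for _sym, tier, *_ in GOI_HIERARCHY:
            counted[tier] = counted.get(tier, 0) + 1
        assert counted == GOI_TIER_SIZES

    def test_gih_contract_on_arbitrary_network(self):
        """The hierarchy builder accepts the published GOI list with any
        user-supplied network and yields one entry per gene."""
        rng = np.random.default_rng(8)
        symbols = goi_symbols()
        edges = [
            (symbols[i], symbols[j])
            for i, j in rng.integers(0, len(symbols), size=(150, 2))
            if i != j
        ]
        net = InteractionNetwork(edges=edges)
        from bihemi.reference_data import goi_annotations

        table = build_gih(net, symbols, annotations=goi_annotations())
        assert len(table.entries) == 114
        assert sum(table.tier_totals.values()) == 114
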