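"""Synthetic generators: determinism, ground-truth recovery, realism checks."""

from __future__ import annotations

import numpy as np
import pytest

from bihemi.bilateral import partition, summarize
from bihemi.datatypes import ConfigurationError
from bihemi.diffexpr import fold_change_records
from bihemi.gih import assign_tier, connection_count, induce_goi_network
from bihemi.simulate import (
    NetworkConfig,
    SimulationConfig,
    generate_expression,
    generate_network,
    scale_class_sizes,
)


def _category_of(truth_class: str) -> str:
    return "unchanged" if truth_class == "null" else truth_class


class TestExpressionGenerator:
    def test_same_seed_identical_output(self):
        ds1, truth1 = generate_expression(SimulationConfig(n_genes=200, class_sizes=scale_class_sizes(0.3), seed=31))
        ds2, truth2 = generate_expression(SimulationConfig(n_genes=200, class_sizes=scale_class_sizes(0.3), seed=31))
        assert np.array_equal(ds1.signal, ds2.signal)
        assert np.array_equal(ds1.call, ds2.call)
        assert truth1.equals(truth2)

    def test_different_seed_differs(self):
        ds1, _ = generate_expression(SimulationConfig(n_genes=200, class_sizes=scale_class_sizes(0.3), seed=31))
        ds2, _ = generate_expression(SimulationConfig(n_genes=200, class_sizes=scale_class_sizes(0.3), seed=32))
        assert not np.array_equal(ds1.signal, ds2.signal)

    def test_output_passes_dataset_validation(self):
        ds, _ = generate_expression(SimulationConfig(n_genes=100, class_sizes=scale_class_sizes(0.2), seed=1))
        ds.validate()  # raises on violation
        assert ds.n_samples == 9

    def test_zero_noise_recovers_planted_classes_exactly(self):
        """At noise 0 the category confusion matrix is diagonal."""
        ds, truth = generate_expression(SimulationConfig(noise_sd=0.0, seed=7))
        cls = {c.gene_id: c.category for c in partition(fold_change_records(ds))}
        for row in truth.itertuples():
            assert cls[row.gene_id] == _category_of(row.planted_class), row.gene_id

    def test_recall_precision_default_noise(self):
        """Changed-gene recall (effects >= 3-fold) and precision both reach
        0.95 at the default noise level."""
        ds, truth = generate_expression(SimulationConfig(seed=11))
        records = {r.gene_id: r for r in fold_change_records(ds)}
        for side, effect_col in (("ipsi", "effect_ipsi"), ("contra", "effect_contra")):
            called = {
                g
                for g, r in records.items()
                if (r.changed_ipsi if side == "ipsi" else r.changed_contra)
            }
            planted = set(
                truth.loc[abs(truth[effect_col]) >= 2.0, "gene_id"]
            )
            strong = set(truth.loc[abs(truth[effect_col]) >= 3.0, "gene_id"])
            recall = len(called & strong) / len(strong)
            precision = len(called & planted) / len(called)
            assert recall >= 0.95, side
            assert precision >= 0.95, side

    def test_summary_reproduces_published_shape(self):
        """Default planted sizes give the 75/25/54/21/95/74 breakdown."""
        ds, _ = generate_expression(SimulationConfig(noise_sd=0.0, seed=2))
        s = summarize(partition(fold_change_records(ds)))
        assert (s.common, s.ipsi_unique, s.contra_unique) == (146, 188, 38)
        assert s.percent["similar"] == 75
        assert s.percent["different"] == 25
        assert s.percent["similar-up"] == 54
        assert s.percent["similar-down"] == 21
        assert s.percent["ipsi-unique-up"] == 95
        assert s.percent["contra-unique-down"] == 74

    def test_effect_estimation_error_shrinks_with_noise(self):
        """Mean |log2 planted - log2 estimated| effect error decreases as
        replicate noise decreases."""
        errors = []
        for noise in (0.3, 0.1, 0.02):
            ds, truth = generate_expression(
                SimulationConfig(n_genes=300, class_sizes=scale_class_sizes(0.5), noise_sd=noise, seed=19)
            )
            fc = {r.gene_id: r.fc_ipsi for r in fold_change_records(ds)}
            signed_log2 = lambda f: np.log2(f) if f >= 1 else -np.log2(-f)
            err = np.mean(
                [
                    abs(signed_log2(fc[g]) - signed_log2(e))
                    for g, e in zip(truth.gene_id, truth.effect_ipsi)
                ]
            )
            errors.append(err)
        assert errors[0] > errors[1] > errors[2]

    def test_null_genes_get_forced_absent_calls(self):
        ds, truth = generate_expression(
            SimulationConfig(n_genes=300, class_sizes=scale_class_sizes(0.3), seed=23, absent_rate=0.5)
        )
        null_ids = set(truth.loc[truth.planted_class == "null", "gene_id"])
        idx = {g: i for i, g in enumerate(ds.gene_ids)}
        all_absent = sum(
            1 for g in null_ids if np.all(ds.call[idx[g]] == "A")
        )
        assert 0.3 < all_absent / len(null_ids) < 0.7

    def test_infeasible_class_sizes_rejected(self):
        with pytest.raises(ConfigurationError, match="n_genes"):
            generate_expression(
                SimulationConfig(n_genes=10, class_sizes={"ipsi-unique-up": 50})
            )


class TestNetworkGenerator:
    def test_same_seed_identical_network(self):
        net1, t1 = generate_network(seed=6)
        net2, t2 = generate_network(seed=6)
        assert net1 == net2
        assert t1 == t2

    def test_zero_rewiring_recovers_all_tiers(self):
        net, truth = generate_network(seed=14)
        sub = induce_goi_network(net, set(truth))
        for node, tier in truth.items():
            assert assign_tier(connection_count(sub, node)) == tier

    def test_default_sizes_give_95_connected_19_orphan(self):
        net, truth = generate_network(seed=0)
        assert net.n_nodes == 114
        connected = {n for n in net.nodes if len(net.neighbors(n)) > 0}
        assert len(connected) == 95
        assert sum(1 for t in truth.values() if t == "orphan") == 19

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_handshake_on_any_seed(self, seed):
        net, _ = generate_network(seed=seed)
        total_degree = sum(len(net.neighbors(n)) for n in net.nodes)
        assert total_degree % 2 == 0
        assert total_degree == 2 * net.n_edges

    def test_rewiring_noise_degrades_recovery_gracefully(self):
        """Tier recovery is perfect at zero noise and declines (but stays
        well above chance) under moderate rewiring."""
        recoveries = []
        for p in (0.0, 0.2, 0.5):
            net, truth = generate_network(
                NetworkConfig(rewire_prob=p), seed=25
            )
            sub = induce_goi_network(net, set(truth))
            ok = sum(
                1
                for n, t in truth.items()
                if assign_tier(connection_count(sub, n)) == t
            )
            recoveries.append(ok / len(truth))
        assert recoveries[0] == 1.0
        assert recoveries[0] >= recoveries[1] >= recoveries[2]
        assert recoveries[2] > 0.25  # above the 4-way chance level

    def test_nongraphical_sequence_rejected(self):
        cfg = NetworkConfig(
            tier_sizes={"primary": 2, "secondary": 0, "peripheral": 0, "orphan": 0},
            degree_ranges={
                "primary": (11, 11),
                "secondary": (5, 10),
                "peripheral": (1, 4),
                "orphan": (0, 0),
            },
        )
        with pytest.raises(ConfigurationError, match="graphical"):
            generate_network(cfg, seed=0)
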