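#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Emulates the bilateral injury design: 3 groups (ipsilateral, contralateral,
naive) x 3 replicate arrays over 1,000 genes, with 372 responsive genes
planted in the published breakdown shape (146 common / 188 ipsi-unique /
38 contra-unique), plus a 114-node interaction network planted with tier
sizes 20/34/41/19. Writes everything, including ground truth, under
results/simulated/.
"""

from pathlib import Path

from bihemi.io import write_expression_table, write_network
from bihemi.simulate import (
    NetworkConfig,
    SimulationConfig,
    generate_expression,
    generate_network,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 20240917


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    config = SimulationConfig(seed=SEED)
    dataset, truth = generate_expression(config)
    write_expression_table(dataset, OUT / "expression.tsv")
    with (OUT / "groups.tsv").open("w") as fh:
        for s in dataset.sample_ids:
            fh.write(f"{s}\t{dataset.group_of_sample[s]}\n")
    truth.to_csv(OUT / "expression_truth.tsv", sep="\t", index=False)
    planted = truth.planted_class.value_counts()
    print(f"expression: {dataset.n_genes} genes x {dataset.n_samples} samples")
    print(f"planted responsive genes: {int((truth.planted_class != 'null').sum())}")
    print(planted.to_string())

    net, tiers = generate_network(NetworkConfig(seed=SEED))
    write_network(net, OUT / "network.sif")
    with (OUT / "network_truth.tsv").open("w") as fh:
        fh.write("symbol\ttier\n")
        for name in sorted(tiers):
            fh.write(f"{name}\t{tiers[name]}\n")
    print(f"\nnetwork: {net.n_nodes} nodes, {net.n_edges} edges")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
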