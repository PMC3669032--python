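"""Gene interaction hierarchy (GIH): rank genes of interest by direct
connections.

Given a curated list of genes of interest (GOI) and any undirected
gene-interaction network, the GOI subnetwork keeps only edges whose both
endpoints are GOI ("direct", first-order connections). Each gene's
connection count is its number of distinct neighbors in that subnetwork,
and the count maps to a tier:

* primary:     more than 10 connections
* secondary:   5-10 connections
* peripheral:  1-4 connections
* orphan:      no connections at all

The resulting table — one row per GOI with count, tier, annotation and the
fold changes from both injury contrasts — is the hierarchy used to
prioritize inflammatory genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .datatypes import COMPARTMENT_ORDER, GeneAnnotation, InteractionNetwork
from .diffexpr import FoldChangeRecord

logger = logging.getLogger(__name__)

TIERS = ("primary", "secondary", "peripheral", "orphan")

#: Default tier boundaries: primary strictly above PRIMARY_GT connections,
#: secondary from SECONDARY_MIN up to PRIMARY_GT inclusive.
PRIMARY_GT = 10
SECONDARY_MIN = 5


def induce_goi_network(
    network: InteractionNetwork, goi: Iterable[str]
) -> InteractionNetwork:
    """Subnetwork on the GOI: edges with both endpoints in the GOI set.

    GOI absent from the input network become isolated nodes (logged), so
    every gene of interest appears in the result exactly once.
    """
    goi = {g.strip() for g in goi}
    if not goi:
        raise ValueError("empty GOI set")
    sub = InteractionNetwork()
    absent = sorted(goi - network.nodes)
    if absent:
        logger.info(
            "%d GOI absent from the network (isolated): %s",
            len(absent),
            ", ".join(absent),
        )
    for g in sorted(goi):
        sub.add_node(g)
    for edge in network.edges:
        a, b = tuple(edge)
        if a in goi and b in goi:
            sub.add_edge(a, b)
    return sub


def connection_count(subnetwork: InteractionNetwork, symbol: str) -> int:
    """Distinct direct neighbors of ``symbol`` in the GOI subnetwork,
    excluding the gene itself."""
    return len(subnetwork.neighbors(symbol) - {symbol})


def assign_tier(
    count: int,
    primary_gt: int = PRIMARY_GT,
    secondary_min: int = SECONDARY_MIN,
) -> str:
    """Map a connection count to its hierarchy tier."""
    if count < 0:
        raise ValueError(f"negative connection count {count}")
    if count > primary_gt:
        return "primary"
    if count >= secondary_min:
        return "secondary"
    if count >= 1:
        return "peripheral"
    return "orphan"


@dataclass
class GIHEntry:
    """One hierarchy row: gene, connections, tier, annotation, fold changes."""

    symbol: str
    connection_count: int
    tier: str
    fc_ipsi: float | None  # None = did not qualify as changed ("~")
    fc_contra: float | None
    compartment: str = "unknown"
    molecule_type: str = "other"
    entrez_name: str = ""


@dataclass
class GIHTable:
    """Hierarchy entries in display order plus per-tier totals."""

    entries: list[GIHEntry]
    tier_totals: dict[str, int]

    @property
    def n_connected(self) -> int:
        """GOI with at least one direct connection."""
        return sum(
            self.tier_totals[t] for t in ("primary", "secondary", "peripheral")
        )

    @property
    def n_orphan(self) -> int:
        return self.tier_totals["orphan"]


def _sort_key(entry: GIHEntry) -> tuple:
    compartment_rank = (
        COMPARTMENT_ORDER.index(entry.compartment)
        if entry.compartment in COMPARTMENT_ORDER
        else len(COMPARTMENT_ORDER)
    )
    return (
        TIERS.index(entry.tier),
        compartment_rank,
        entry.molecule_type,
        entry.symbol,
    )


def build_gih(
    network: InteractionNetwork,
    goi: Iterable[str],
    annotations: Mapping[str, GeneAnnotation] | None = None,
    fold_changes: Mapping[str, FoldChangeRecord] | None = None,
    primary_gt: int = PRIMARY_GT,
    secondary_min: int = SECONDARY_MIN,
) -> GIHTable:
    """Assemble the full hierarchy table for a GOI list.

    Fold-change cells are ``None`` (rendered "~") when the gene has no
    record or did not qualify as changed on that side. A GOI without an
    annotation is emitted with compartment "unknown" and a warning.
    Ordering is deterministic: tier, then compartment (outermost first),
    then molecule type, then symbol.
    """
    annotations = annotations or {}
    fold_changes = fold_changes or {}
    sub = induce_goi_network(network, goi)
    unannotated = sorted(sub.nodes - set(annotations))
    if annotations and unannotated:
        logger.warning(
            "%d GOI lack annotations (compartment set to unknown): %s",
            len(unannotated),
            ", ".join(unannotated[:10]) + ("..." if len(unannotated) > 10 else ""),
        )
    entries = []
    for symbol in sorted(sub.nodes):
        count = connection_count(sub, symbol)
        ann = annotations.get(symbol)
        if ann is None:
            ann = GeneAnnotation(gene_id=symbol, symbol=symbol)
        fc = fold_changes.get(symbol)
        entries.append(
            GIHEntry(
                symbol=symbol,
                connection_count=count,
                tier=assign_tier(count, primary_gt, secondary_min),
                fc_ipsi=fc.fc_ipsi if fc is not None and fc.changed_ipsi else None,
                fc_contra=(
                    fc.fc_contra if fc is not None and fc.changed_contra else None
                ),
                compartment=ann.compartment,
                molecule_type=ann.molecule_type,
                entrez_name=ann.entrez_name,
            )
        )
    entries.sort(key=_sort_key)
    totals = {t: sum(1 for e in entries if e.tier == t) for t in TIERS}
    return GIHTable(entries=entries, tier_totals=totals)
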