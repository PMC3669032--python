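"""Shared data types for the bilateral brain-injury expression pipeline.

The pipeline compares gene expression in three groups of brain tissue —
ipsilateral (same side as a unilateral cortical impact), contralateral
(opposite side), and naive (uninjured controls) — and everything downstream
consumes the types defined here: a replicate-level expression matrix with
per-sample detection calls, gene annotations, named gene sets, and an
undirected gene-interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

#: Group labels used throughout. "ipsilateral" is the injured hemisphere,
#: "contralateral" the mirror-image uninjured hemisphere, "naive" the
#: uninjured control animals.
GROUPS = ("ipsilateral", "contralateral", "naive")

#: Valid detection calls: Present / Marginal / Absent.
CALL_SYMBOLS = frozenset({"P", "M", "A"})

#: Canonical ordering of cellular compartments (outermost first), used for
#: deterministic table layout.
COMPARTMENT_ORDER = (
    "extracellular space",
    "plasma membrane",
    "cytoplasm",
    "nucleus",
    "unknown",
)

#: Contrast labels: fold change of injured-side groups against naive.
TBI_I = "TBI-I"  # ipsilateral vs naive
TBI_C = "TBI-C"  # contralateral vs naive


class FormatError(ValueError):
    """An input file violates its format contract."""


class ConfigurationError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group fold-change contrast (case vs control)."""

    case_group: str
    control_group: str
    label: str

    def __post_init__(self) -> None:
        if self.case_group == self.control_group:
            raise ConfigurationError(
                f"contrast {self.label!r}: case and control are both "
                f"{self.case_group!r}"
            )


#: The study's two contrasts.
CONTRAST_IPSI = ContrastSpec("ipsilateral", "naive", TBI_I)
CONTRAST_CONTRA = ContrastSpec("contralateral", "naive", TBI_C)


@dataclass
class ExpressionDataset:
    """Genes x samples signal matrix with detection calls and group labels.

    Parameters
    ----------
    gene_ids
        Row identifiers (probe sets or gene symbols); order defines row order.
    sample_ids
        Column identifiers; order defines column order.
    group_of_sample
        Mapping from every sample id to its group label.
    signal
        Non-negative expression signals, shape ``(len(gene_ids), len(sample_ids))``.
    call
        Detection calls in {P, M, A}, same shape as ``signal``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    group_of_sample: dict[str, str]
    signal: np.ndarray
    call: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.call = np.asarray(self.call, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_genes, n_samples = len(self.gene_ids), len(self.sample_ids)
        if self.signal.shape != (n_genes, n_samples):
            raise FormatError(
                f"signal shape {self.signal.shape} does not match "
                f"{n_genes} genes x {n_samples} samples"
            )
        if self.call.shape != self.signal.shape:
            raise FormatError(
                f"call shape {self.call.shape} differs from signal shape "
                f"{self.signal.shape}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_samples:
            raise FormatError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.group_of_sample]
        if missing:
            raise ConfigurationError(
                f"samples missing from group map: {', '.join(missing)}"
            )
        if np.any(~np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise FormatError("signals must be finite and non-negative")
        bad = {str(c) for c in self.call.ravel()} - CALL_SYMBOLS
        if bad:
            raise FormatError(
                f"unknown detection call symbol(s): {', '.join(sorted(bad))}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_in_group(self, group: str) -> list[str]:
        """Sample ids belonging to ``group``, in column order."""
        return [s for s in self.sample_ids if self.group_of_sample[s] == group]

    def column_indices(self, group: str) -> np.ndarray:
        """Column indices of the samples in ``group``."""
        idx = [
            j
            for j, s in enumerate(self.sample_ids)
            if self.group_of_sample[s] == group
        ]
        if not idx:
            raise ConfigurationError(f"group {group!r} has no samples")
        return np.asarray(idx, dtype=int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and {s: self.group_of_sample[s] for s in self.sample_ids}
            == {s: other.group_of_sample[s] for s in other.sample_ids}
            and np.allclose(self.signal, other.signal)
            and np.array_equal(self.call, other.call)
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Annotation for one gene: symbol, free-text name, compartment, type."""

    gene_id: str
    symbol: str
    entrez_name: str = ""
    compartment: str = "unknown"
    molecule_type: str = "other"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENT_ORDER:
            raise FormatError(
                f"unknown cellular compartment {self.compartment!r} for "
                f"{self.gene_id!r}; expected one of {COMPARTMENT_ORDER}"
            )


class GeneSetCollection:
    """Named gene sets, one of which is the inflammatory-response (IR) set."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        ir_set_name: str | None = None,
    ) -> None:
        self.sets: dict[str, frozenset[str]] = {}
        for name, members in sets.items():
            cleaned = frozenset(m.strip() for m in members)
            if "" in cleaned:
                raise FormatError(f"gene set {name!r} contains an empty symbol")
            self.sets[name] = cleaned
        self.ir_set_name = ir_set_name
        if ir_set_name is not None and ir_set_name not in self.sets:
            raise ConfigurationError(
                f"designated IR set {ir_set_name!r} not present in collection"
            )

    @property
    def ir_set(self) -> frozenset[str]:
        if self.ir_set_name is None:
            raise ConfigurationError("no IR set designated for this collection")
        return self.sets[self.ir_set_name]

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


class InteractionNetwork:
    """Undirected gene-interaction network (no self-loops, deduplicated).

    Thin wrapper over :class:`networkx.Graph` that enforces the invariants
    the hierarchy analysis relies on: symbols are stripped strings, edges are
    unordered pairs stored once, and self-loops are rejected at insertion.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.graph = nx.Graph()
        for n in nodes:
            self.add_node(n)
        for a, b in edges:
            self.add_edge(a, b)

    def add_node(self, symbol: str) -> None:
        symbol = symbol.strip()
        if not symbol:
            raise FormatError("blank node name")
        self.graph.add_node(symbol)

    def add_edge(self, a: str, b: str) -> bool:
        """Add an undirected edge; returns False for a (dropped) self-loop."""
        a, b = a.strip(), b.strip()
        if not a or not b:
            raise FormatError("blank node name in edge")
        if a == b:
            self.graph.add_node(a)  # keep the node, drop the loop
            return False
        self.graph.add_edge(a, b)
        return True

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, symbol: str) -> set[str]:
        if symbol not in self.graph:
            raise KeyError(f"unknown symbol {symbol!r}")
        return set(self.graph.neighbors(symbol))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges
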