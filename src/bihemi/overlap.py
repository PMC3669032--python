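"""Overlap of biological-function gene sets with the inflammatory-response set.

For each function, the statistic is the share of its genes that are also
inflammatory-response (IR) genes: ``|function ∩ IR| / |function|`` as an
integer percentage (half-up). The cumulative overlap pools counts across
functions — total shared genes over total function genes — rather than
averaging the per-function percentages. A one-sided hypergeometric tail
(Fisher's exact test for over-representation) gives an optional enrichment
p-value against a stated gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from ._rounding import percent_half_up, round_half_up


@dataclass(frozen=True)
class OverlapRecord:
    """One function's overlap with the IR set."""

    function_name: str
    unique_genes: int  # genes in the function set
    overlap_ir: int  # genes shared with the IR set
    percent: int  # integer half-up of 100 * overlap / unique

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_ir <= self.unique_genes:
            raise ValueError(
                f"{self.function_name}: overlap {self.overlap_ir} outside "
                f"[0, {self.unique_genes}]"
            )


def overlap_record(
    function_name: str, unique_genes: int, overlap_ir: int
) -> OverlapRecord:
    """Build an :class:`OverlapRecord` from counts."""
    if unique_genes <= 0:
        raise ValueError(f"{function_name}: empty function set")
    return OverlapRecord(
        function_name,
        unique_genes,
        overlap_ir,
        percent_half_up(overlap_ir, unique_genes),
    )


def overlap_percent(
    function_name: str,
    function_set: Iterable[str],
    ir_set: Iterable[str],
) -> OverlapRecord:
    """Overlap of one function gene set with the IR set.

    The denominator is the function set size only; the IR set size never
    enters the percentage.
    """
    fset = set(function_set)
    if not fset:
        raise ValueError(f"{function_name}: empty function set")
    return overlap_record(function_name, len(fset), len(fset & set(ir_set)))


def cumulative_overlap(records: Sequence[OverlapRecord]) -> float:
    """Pooled overlap percentage across functions, one decimal (half-up).

    ``100 * (sum of overlap counts) / (sum of function sizes)`` — pooling
    counts, not averaging percentages, so large functions weigh more.
    """
    if not records:
        raise ValueError("no overlap records")
    total_unique = sum(r.unique_genes for r in records)
    total_overlap = sum(r.overlap_ir for r in records)
    if total_unique == 0:
        raise ValueError("zero total function size")
    return round_half_up(100.0 * total_overlap / total_unique, 1)


def enrichment_pvalue(
    overlap: int, function_size: int, ir_size: int, universe: int
) -> float:
    """One-sided over-representation p-value, P[X >= overlap].

    X is hypergeometric: draw ``function_size`` genes without replacement
    from a universe of ``universe`` genes of which ``ir_size`` are IR.
    """
    if not (
        0 <= overlap <= min(function_size, ir_size)
        and max(function_size, ir_size) <= universe
    ):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, "
            f"function={function_size}, ir={ir_size}, universe={universe}"
        )
    # sf(k) = P[X > k], so P[X >= overlap] = sf(overlap - 1)
    return float(hypergeom.sf(overlap - 1, universe, ir_size, function_size))
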