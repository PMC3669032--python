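"""Presence filtering and signed fold changes for the two injury contrasts.

A gene qualifies for analysis when it is detected ("P") in all replicates of
at least one injured-side group (all ipsilateral or all contralateral
samples). Fold changes are signed ratios of group-mean signals: a gene at
mean 200 in cases vs 100 in controls has fold change +2.0; at 50 vs 200,
-4.0 (the ratio is folded to magnitude >= 1, the sign giving direction). A
gene is "changed" on a side when it passes the presence rule and the fold
magnitude reaches the threshold — 2-fold or more by default, boundary
included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .datatypes import (
    CONTRAST_CONTRA,
    CONTRAST_IPSI,
    TBI_C,
    TBI_I,
    ConfigurationError,
    ExpressionDataset,
)

Summary = Literal["mean", "geomean"]


@dataclass
class FoldChangeRecord:
    """Per-gene signed fold changes for both contrasts plus qualifying flags."""

    gene_id: str
    fc_ipsi: float
    fc_contra: float
    present_ipsi: bool
    present_contra: bool
    changed_ipsi: bool
    changed_contra: bool

    @property
    def presence_pass(self) -> bool:
        return self.present_ipsi or self.present_contra


def group_mean(
    dataset: ExpressionDataset, group: str, summary: Summary = "mean"
) -> np.ndarray:
    """Per-gene summary of replicate signals within one group.

    Arithmetic mean by default; geometric mean (of signals + a small floor to
    avoid log(0)) as an alternative for strongly skewed replicates.
    """
    cols = dataset.column_indices(group)
    block = dataset.signal[:, cols]
    if summary == "mean":
        return block.mean(axis=1)
    if summary == "geomean":
        return np.exp(np.log(np.maximum(block, 1e-12)).mean(axis=1))
    raise ConfigurationError(f"unknown summary {summary!r}")


def signed_fold_change(mean_case: float, mean_control: float) -> float:
    """Signed fold change between two positive group means.

    Returns ``mean_case / mean_control`` when the case mean is the larger
    (or equal: ties map to +1.0), else ``-(mean_control / mean_case)``; the
    magnitude is therefore always >= 1 and the sign gives the direction.
    """
    if not (mean_case > 0 and mean_control > 0):
        raise ValueError(
            f"group means must be positive, got ({mean_case}, {mean_control})"
        )
    if mean_case >= mean_control:
        return mean_case / mean_control
    return -(mean_control / mean_case)


def presence_pass(
    calls_ipsi: Sequence[str], calls_contra: Sequence[str]
) -> bool:
    """True iff the gene is "P" in every ipsilateral sample or every
    contralateral sample. Marginal ("M") counts as not present."""
    all_p = lambda calls: len(calls) > 0 and all(c == "P" for c in calls)
    return all_p(list(calls_ipsi)) or all_p(list(calls_contra))


def fold_change_records(
    dataset: ExpressionDataset,
    threshold: float = 2.0,
    summary: Summary = "mean",
) -> list[FoldChangeRecord]:
    """Compute both contrasts for every gene and apply the change filter.

    For each gene: TBI-I = ipsilateral vs naive, TBI-C = contralateral vs
    naive, both as signed fold changes of group-mean signals. ``changed_*``
    requires the presence rule (all-P on at least one injured side) and
    ``|fc| >= threshold``.
    """
    if threshold < 1:
        raise ConfigurationError(f"threshold must be >= 1, got {threshold}")
    mean_ipsi = group_mean(dataset, CONTRAST_IPSI.case_group, summary)
    mean_contra = group_mean(dataset, CONTRAST_CONTRA.case_group, summary)
    mean_naive = group_mean(dataset, CONTRAST_IPSI.control_group, summary)

    ipsi_cols = dataset.column_indices("ipsilateral")
    contra_cols = dataset.column_indices("contralateral")

    records = []
    for i, gene in enumerate(dataset.gene_ids):
        fc_i = signed_fold_change(float(mean_ipsi[i]), float(mean_naive[i]))
        fc_c = signed_fold_change(float(mean_contra[i]), float(mean_naive[i]))
        pres_i = bool(np.all(dataset.call[i, ipsi_cols] == "P"))
        pres_c = bool(np.all(dataset.call[i, contra_cols] == "P"))
        passes = pres_i or pres_c
        records.append(
            FoldChangeRecord(
                gene_id=gene,
                fc_ipsi=fc_i,
                fc_contra=fc_c,
                present_ipsi=pres_i,
                present_contra=pres_c,
                changed_ipsi=passes and abs(fc_i) >= threshold,
                changed_contra=passes and abs(fc_c) >= threshold,
            )
        )
    return records


def changed_genes(
    records: Iterable[FoldChangeRecord],
    side: str,
    threshold: float = 2.0,
) -> list[str]:
    """Genes changed on one side: presence rule met and |fc| >= threshold
    ("2-fold or more" is inclusive of the boundary)."""
    if threshold < 1:
        raise ConfigurationError(f"threshold must be >= 1, got {threshold}")
    if side not in (TBI_I, TBI_C):
        raise ConfigurationError(f"side must be {TBI_I!r} or {TBI_C!r}")
    out = []
    for r in records:
        fc = r.fc_ipsi if side == TBI_I else r.fc_contra
        if r.presence_pass and abs(fc) >= threshold:
            out.append(r.gene_id)
    return out
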