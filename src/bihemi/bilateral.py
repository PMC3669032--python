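"""Bilateral comparison of the two injury contrasts.

The central statistic is the hemispheric fold-ratio: for a gene changed on
both sides of the brain, how much stronger was the ipsilateral (local)
response than the contralateral (remote) one? On a linear expression scale,
writing ``linear(f) = f`` for an up-regulated signed fold change (f >= 1)
and ``linear(f) = 1/|f|`` for a down-regulated one (f <= -1), the ratio is

    ratio = linear(fc_ipsi) / linear(fc_contra)

which resolves case by case to:

* both up:            fc_ipsi / fc_contra
* both down:          fc_contra / fc_ipsi
* up ipsi, down contra: fc_ipsi * |fc_contra|
* down ipsi, up contra: 1 / (|fc_ipsi| * fc_contra)   (always < 1)

A common gene with ratio strictly greater than 1.75 is classified as
changing "differently" between hemispheres; otherwise "similarly". Genes
changed on exactly one side are "unique" to that side. The partition plus
its summary percentages reproduce the study-style breakdown (common
similar/different, up/down per side).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from ._rounding import percent_half_up
from .datatypes import ConfigurationError
from .diffexpr import FoldChangeRecord

RATIO_THRESHOLD = 1.75

Category = Literal[
    "common-similar-up",
    "common-similar-down",
    "common-different",
    "ipsi-unique-up",
    "ipsi-unique-down",
    "contra-unique-up",
    "contra-unique-down",
    "unchanged",
]

CATEGORIES: tuple[Category, ...] = (
    "common-similar-up",
    "common-similar-down",
    "common-different",
    "ipsi-unique-up",
    "ipsi-unique-down",
    "contra-unique-up",
    "contra-unique-down",
    "unchanged",
)

RatioMode = Literal["faithful", "symmetric"]


def _linear(fc: float) -> float:
    """Signed fold change -> linear-scale expression ratio (case/control)."""
    return fc if fc >= 1 else 1.0 / abs(fc)


def fold_ratio(
    fc_ipsi: float, fc_contra: float, mode: RatioMode = "faithful"
) -> float:
    """Hemispheric divergence ratio of two signed fold changes.

    Both inputs must have magnitude >= 1 (the signed convention). The
    default "faithful" mode is ``linear(fc_ipsi) / linear(fc_contra)``
    exactly; for the one sign case this leaves below 1 (gene down
    ipsilaterally, up contralaterally) the "symmetric" mode instead returns
    ``max(r, 1/r)`` so such divergent genes also exceed the classification
    threshold.
    """
    for name, fc in (("fc_ipsi", fc_ipsi), ("fc_contra", fc_contra)):
        if abs(fc) < 1:
            raise ValueError(
                f"{name} must have magnitude >= 1 under the signed "
                f"convention, got {fc}"
            )
    r = _linear(fc_ipsi) / _linear(fc_contra)
    if mode == "symmetric":
        return max(r, 1.0 / r)
    if mode != "faithful":
        raise ConfigurationError(f"unknown ratio mode {mode!r}")
    return r


def classify_common(ratio: float, threshold: float = RATIO_THRESHOLD) -> str:
    """"different" iff the ratio strictly exceeds the threshold, else "similar"."""
    return "different" if ratio > threshold else "similar"


@dataclass
class BilateralClassification:
    """One gene's place in the common/unique x up/down partition."""

    gene_id: str
    category: Category
    ratio: float | None = None  # present iff the gene is common
    fc_ipsi: float | None = None
    fc_contra: float | None = None


def partition(
    records: Iterable[FoldChangeRecord],
    restrict_to: set[str] | frozenset[str] | None = None,
    ratio_threshold: float = RATIO_THRESHOLD,
    ratio_mode: RatioMode = "faithful",
) -> list[BilateralClassification]:
    """Assign every (optionally restricted) gene to exactly one category.

    Common genes (changed on both sides) get a fold ratio and are split
    similar/different at the threshold; similar genes are sub-labeled
    up/down by the sign of the ipsilateral fold change. With the default
    2-fold change filter, a gene up ipsilaterally and down contralaterally
    always exceeds the ratio threshold (ratio >= 4) and lands in
    common-different; the opposite sign pattern has faithful ratio <= 1/4
    and is labeled "similar" by the ipsilateral direction unless the
    symmetric ratio mode is selected. Unique genes are labeled by side and
    direction; everything else is "unchanged".
    """
    out: list[BilateralClassification] = []
    for r in records:
        if restrict_to is not None and r.gene_id not in restrict_to:
            continue
        if r.changed_ipsi and r.changed_contra:
            ratio = fold_ratio(r.fc_ipsi, r.fc_contra, mode=ratio_mode)
            if classify_common(ratio, ratio_threshold) == "different":
                category: Category = "common-different"
            elif r.fc_ipsi >= 1:
                category = "common-similar-up"
            else:
                category = "common-similar-down"
            out.append(
                BilateralClassification(
                    r.gene_id, category, ratio, r.fc_ipsi, r.fc_contra
                )
            )
        elif r.changed_ipsi:
            category = (
                "ipsi-unique-up" if r.fc_ipsi >= 1 else "ipsi-unique-down"
            )
            out.append(
                BilateralClassification(
                    r.gene_id, category, None, r.fc_ipsi, None
                )
            )
        elif r.changed_contra:
            category = (
                "contra-unique-up" if r.fc_contra >= 1 else "contra-unique-down"
            )
            out.append(
                BilateralClassification(
                    r.gene_id, category, None, None, r.fc_contra
                )
            )
        else:
            out.append(BilateralClassification(r.gene_id, "unchanged"))
    return out


#: Marker for a percentage whose denominator is zero.
UNDEFINED = "undefined"


@dataclass
class PartitionSummary:
    """Category counts and the derived integer percentages.

    Percentage denominators follow the breakdown layout: similar, different
    and the similar up/down splits are fractions of the common total; unique
    up/down splits are fractions of their own side's unique total. A zero
    denominator yields the string marker "undefined" instead of an error.
    """

    counts: dict[str, int]
    common: int
    ipsi_unique: int
    contra_unique: int
    total_changed: int
    percent: dict[str, int | str]


def _pct(num: int, den: int) -> int | str:
    return percent_half_up(num, den) if den else UNDEFINED


def summarize(
    classifications: Sequence[BilateralClassification],
) -> PartitionSummary:
    """Summarize a partition into counts and display percentages."""
    counts = {c: 0 for c in CATEGORIES}
    for cl in classifications:
        counts[cl.category] += 1
    similar = counts["common-similar-up"] + counts["common-similar-down"]
    common = similar + counts["common-different"]
    ipsi_unique = counts["ipsi-unique-up"] + counts["ipsi-unique-down"]
    contra_unique = counts["contra-unique-up"] + counts["contra-unique-down"]
    percent: dict[str, int | str] = {
        "similar": _pct(similar, common),
        "different": _pct(counts["common-different"], common),
        "similar-up": _pct(counts["common-similar-up"], common),
        "similar-down": _pct(counts["common-similar-down"], common),
        "ipsi-unique-up": _pct(counts["ipsi-unique-up"], ipsi_unique),
        "ipsi-unique-down": _pct(counts["ipsi-unique-down"], ipsi_unique),
        "contra-unique-up": _pct(counts["contra-unique-up"], contra_unique),
        "contra-unique-down": _pct(counts["contra-unique-down"], contra_unique),
    }
    return PartitionSummary(
        counts=counts,
        common=common,
        ipsi_unique=ipsi_unique,
        contra_unique=contra_unique,
        total_changed=common + ipsi_unique + contra_unique,
        percent=percent,
    )
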