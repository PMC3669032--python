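"""Synthetic expression datasets and interaction networks with known truth.

The expression generator emulates the structure of the study design this
pipeline targets: three groups (ipsilateral, contralateral, naive) of three
replicate arrays each, MAS5-style positive signals, Present/Absent
detection calls, and a planted set of responsive genes whose bilateral
behavior spans every category the classifier must distinguish (common
similar up/down, common different, unique per side, null). The network
generator plants a degree sequence matching the hierarchy's tier structure
so tier recovery can be checked exactly.

Both generators are fully deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .bilateral import RATIO_THRESHOLD
from .datatypes import ConfigurationError, ExpressionDataset, InteractionNetwork
from .gih import TIERS

#: Category labels a planted gene can carry ("null" = unresponsive).
PLANTED_CLASSES = (
    "common-similar-up",
    "common-similar-down",
    "common-different",
    "ipsi-unique-up",
    "ipsi-unique-down",
    "contra-unique-up",
    "contra-unique-down",
    "null",
)

#: Default planted class sizes: the published IR breakdown (146 common genes
#: split 79 similar-up / 30 similar-down / 37 different; 188 ipsi-unique
#: split 179 up / 9 down; 38 contra-unique split 10 up / 28 down).
DEFAULT_CLASS_SIZES = {
    "common-similar-up": 79,
    "common-similar-down": 30,
    "common-different": 37,
    "ipsi-unique-up": 179,
    "ipsi-unique-down": 9,
    "contra-unique-up": 10,
    "contra-unique-down": 28,
}


def scale_class_sizes(fraction: float) -> dict[str, int]:
    """Default planted class sizes shrunk proportionally (each kept >= 1),
    for small test datasets that preserve the full class structure."""
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    return {
        cls: max(1, round(n * fraction)) for cls, n in DEFAULT_CLASS_SIZES.items()
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic expression experiment.

    ``baseline_loc``/``baseline_scale`` parameterize the log-normal baseline
    signal (natural-log units; the default centers signals near 1000 with
    moderate spread, a plausible MAS5 scale). ``noise_sd`` is the standard
    deviation of multiplicative replicate noise in natural-log units.
    Effect magnitudes are fold units: similar-class genes get effects in
    ``similar_effect_range`` with a within-pair ratio at most
    ``similar_max_ratio`` (kept below the 1.75 classification threshold);
    different-class and unique-class genes draw from
    ``changed_effect_range`` with the divergence ratio at least
    ``different_min_ratio``. ``call_floor`` is the absolute signal below
    which a detection call is Absent; ``absent_rate`` is the fraction of
    null genes forced Absent in every sample. Down-effects are capped at
    8-fold so planted means stay well above the call floor.
    """

    n_genes: int = 1000
    replicates: int = 3
    baseline_loc: float = np.log(1000.0)
    baseline_scale: float = 0.5
    noise_sd: float = 0.1
    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    similar_effect_range: tuple[float, float] = (2.5, 8.0)
    similar_max_ratio: float = 1.4
    changed_effect_range: tuple[float, float] = (2.5, 8.0)
    different_min_ratio: float = 2.5
    call_floor: float = 10.0
    absent_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.class_sizes) - set(PLANTED_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown planted class(es): {unknown}")
        n_planted = sum(self.class_sizes.values())
        if n_planted > self.n_genes:
            raise ConfigurationError(
                f"planted class sizes sum to {n_planted} > n_genes={self.n_genes}"
            )
        if self.replicates < 1:
            raise ConfigurationError("need at least one replicate per group")
        if self.similar_effect_range[0] < 2 or self.changed_effect_range[0] < 2:
            raise ConfigurationError("changed-class effects must be >= 2-fold")
        if self.similar_max_ratio >= RATIO_THRESHOLD:
            raise ConfigurationError(
                "similar-class ratio bound must stay below the "
                f"{RATIO_THRESHOLD} classification threshold"
            )
        if self.different_min_ratio <= RATIO_THRESHOLD:
            raise ConfigurationError(
                "different-class ratio bound must exceed the "
                f"{RATIO_THRESHOLD} classification threshold"
            )
        if not 0 <= self.absent_rate <= 1:
            raise ConfigurationError("absent_rate must be in [0, 1]")


def _linear(effect: float) -> float:
    """Signed fold effect -> multiplicative factor on the baseline mean."""
    return effect if effect >= 1 else 1.0 / abs(effect)


def _draw_effects(
    cls: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Planted signed (ipsi, contra) effects for one gene of class ``cls``.

    Magnitudes are capped at 8-fold (keeps down-regulated means above the
    detection floor). For "common-different" one of three divergence
    patterns is drawn — both up, both down (contralateral decrease larger),
    or up-ipsi/down-contra — each guaranteeing a fold-ratio above the
    classification threshold.
    """
    lo, hi = config.similar_effect_range
    clo, chi = config.changed_effect_range
    if cls in ("common-similar-up", "common-similar-down"):
        base = rng.uniform(lo, hi)
        r = rng.uniform(1.0, config.similar_max_ratio)
        pair = sorted([base, min(max(base / r, 2.0), 8.0)], reverse=True)
        if rng.random() < 0.5:
            pair = pair[::-1]
        sign = 1.0 if cls.endswith("up") else -1.0
        return sign * pair[0], sign * pair[1]
    if cls == "common-different":
        pattern = rng.choice(["up-up", "down-down", "up-down"])
        small = rng.uniform(2.0, 3.0)
        big = min(small * rng.uniform(config.different_min_ratio, 3.5), 8.0)
        if pattern == "up-up":
            return big, small
        if pattern == "down-down":
            return -small, -big  # larger remote decrease
        return rng.uniform(2.0, 5.0), -rng.uniform(2.0, 5.0)
    if cls.startswith("ipsi-unique"):
        sign = 1.0 if cls.endswith("up") else -1.0
        return sign * rng.uniform(clo, chi), 1.0
    if cls.startswith("contra-unique"):
        sign = 1.0 if cls.endswith("up") else -1.0
        return 1.0, sign * rng.uniform(clo, chi)
    return 1.0, 1.0  # null


def generate_expression(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Generate a replicate-level dataset plus its ground-truth table.

    Returns the dataset (3 groups x ``replicates`` samples) and a frame with
    one row per gene: planted class, signed effects, baseline mean.
    ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    classes = np.array(
        [
            cls
            for cls, size in config.class_sizes.items()
            for _ in range(size)
        ]
        + ["null"] * (config.n_genes - sum(config.class_sizes.values())),
        dtype=object,
    )
    rng.shuffle(classes)

    baseline = rng.lognormal(config.baseline_loc, config.baseline_scale, config.n_genes)
    effects = np.array(
        [_draw_effects(str(c), config, rng) for c in classes], dtype=float
    )

    groups = ("ipsilateral", "contralateral", "naive")
    sample_ids = [
        f"{g[:6]}_{r + 1}" for g in groups for r in range(config.replicates)
    ]
    group_of_sample = {
        s: g for g in groups for s in sample_ids if s.startswith(g[:6])
    }

    factor = np.column_stack(
        [
            [_linear(e) for e in effects[:, 0]],  # ipsilateral
            [_linear(e) for e in effects[:, 1]],  # contralateral
            np.ones(config.n_genes),  # naive
        ]
    )
    means = baseline[:, None] * factor  # genes x 3 groups

    n_samples = 3 * config.replicates
    noise = (
        rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
        if config.noise_sd > 0
        else np.zeros((config.n_genes, n_samples))
    )
    group_idx = np.repeat(np.arange(3), config.replicates)
    signal = means[:, group_idx] * np.exp(noise)

    call = np.where(signal >= config.call_floor, "P", "A").astype(object)
    is_null = classes == "null"
    forced = is_null & (rng.random(config.n_genes) < config.absent_rate)
    call[forced, :] = "A"

    dataset = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        group_of_sample=group_of_sample,
        signal=signal,
        call=call,
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_class": classes,
            "effect_ipsi": effects[:, 0],
            "effect_contra": effects[:, 1],
            "baseline": baseline,
        }
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# network generation


#: Default degree window per tier; consistent with the tier rule
#: (primary > 10, secondary 5-10, peripheral 1-4, orphan 0).
DEFAULT_DEGREE_RANGES = {
    "primary": (11, 18),
    "secondary": (5, 10),
    "peripheral": (1, 4),
    "orphan": (0, 0),
}

#: Default tier sizes: the published hierarchy's 20/34/41/19.
DEFAULT_TIER_SIZES = {"primary": 20, "secondary": 34, "peripheral": 41, "orphan": 19}


@dataclass(frozen=True)
class NetworkConfig:
    """Planted tier sizes, per-tier degree windows and rewiring noise."""

    tier_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TIER_SIZES)
    )
    degree_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DEGREE_RANGES)
    )
    rewire_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.tier_sizes) - set(TIERS)
        if unknown:
            raise ConfigurationError(f"unknown tier(s): {unknown}")
        for tier, (lo, hi) in self.degree_ranges.items():
            if lo > hi or lo < 0:
                raise ConfigurationError(
                    f"bad degree range for {tier}: ({lo}, {hi})"
                )
        if not 0 <= self.rewire_prob <= 1:
            raise ConfigurationError("rewire_prob must be in [0, 1]")


def generate_network(
    config: NetworkConfig | None = None,
    seed: int | None = None,
) -> tuple[InteractionNetwork, dict[str, str]]:
    """Generate a network realizing a planted per-tier degree sequence.

    Degrees are drawn within each tier's window, realized exactly by a
    Havel-Hakimi construction (a simple graph, no self-loops or
    multi-edges), then shuffled by seeded degree-preserving double-edge
    swaps so the topology is random while every node keeps its planted
    degree. ``rewire_prob`` then rewires each edge endpoint with that
    probability — this noise *does* perturb degrees, which is its purpose.

    Returns the network and the planted tier per node. Raises with a hint
    if the drawn degree sequence is not graphical.
    """
    config = config or NetworkConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    names: list[str] = []
    truth: dict[str, str] = {}
    degrees: list[int] = []
    i = 0
    for tier in TIERS:
        lo, hi = config.degree_ranges.get(tier, (0, 0))
        for _ in range(config.tier_sizes.get(tier, 0)):
            name = f"GOI{i:03d}"
            names.append(name)
            truth[name] = tier
            degrees.append(int(rng.integers(lo, hi + 1)))
            i += 1

    # parity fix: total degree must be even; nudge one node within its window
    if sum(degrees) % 2 == 1:
        for j, name in enumerate(names):
            lo, hi = config.degree_ranges[truth[name]]
            if degrees[j] < hi:
                degrees[j] += 1
                break
            if degrees[j] > lo and degrees[j] > 1:
                degrees[j] -= 1
                break
        else:
            raise ConfigurationError("cannot fix degree parity within tier windows")

    if not nx.is_graphical(degrees):
        raise ConfigurationError(
            "planted degree sequence is not graphical; reduce primary degrees "
            "or enlarge the lower tiers"
        )

    positive = [j for j, d in enumerate(degrees) if d > 0]
    sub_degrees = [degrees[j] for j in positive]
    g = nx.havel_hakimi_graph(sub_degrees)
    # Havel-Hakimi gives node k degree sub_degrees[k]; verify then relabel.
    for k in range(len(positive)):
        if g.degree(k) != sub_degrees[k]:
            raise AssertionError("degree sequence not realized exactly")
    g = nx.relabel_nodes(g, {k: names[positive[k]] for k in range(len(positive))})

    n_edges = g.number_of_edges()
    if n_edges > 1:
        swap_seed = int(rng.integers(0, 2**31 - 1))
        nx.double_edge_swap(
            g,
            nswap=4 * n_edges,
            max_tries=200 * n_edges,
            seed=swap_seed,
        )

    if config.rewire_prob > 0:
        all_names = list(names)
        for a, b in list(g.edges):
            if rng.random() < config.rewire_prob:
                g.remove_edge(a, b)
                keep = a if rng.random() < 0.5 else b
                candidates = [
                    n for n in all_names if n != keep and not g.has_edge(keep, n)
                ]
                if candidates:
                    g.add_edge(keep, candidates[int(rng.integers(len(candidates)))])

    net = InteractionNetwork(nodes=names, edges=list(g.edges))
    return net, truth
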