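"""Shared fixtures: small hand-written and seeded random datasets."""

from __future__ import annotations

import numpy as np
import pytest

from bihemi.datatypes import ExpressionDataset


@pytest.fixture
def group_map() -> dict[str, str]:
    return {
        **{f"ipsi_{i}": "ipsilateral" for i in (1, 2, 3)},
        **{f"contra_{i}": "contralateral" for i in (1, 2, 3)},
        **{f"naive_{i}": "naive" for i in (1, 2, 3)},
    }


@pytest.fixture
def small_dataset(group_map) -> ExpressionDataset:
    """3 genes x 9 samples: one up-ipsi gene, one down-both gene, one flat."""
    samples = list(group_map)
    signal = np.array(
        [
            # ipsi x3, contra x3, naive x3
            [400, 440, 360, 110, 100, 90, 100, 110, 90],  # up 4x ipsi
            [25, 25, 25, 12, 13, 11, 100, 100, 100],  # down both sides
            [100, 100, 100, 100, 100, 100, 100, 100, 100],  # flat
        ],
        dtype=float,
    )
    call = np.full((3, 9), "P", dtype=object)
    return ExpressionDataset(
        gene_ids=["GENE_UP", "GENE_DOWN", "GENE_FLAT"],
        sample_ids=samples,
        group_of_sample=group_map,
        signal=signal,
        call=call,
    )


@pytest.fixture
def random_dataset(group_map) -> ExpressionDataset:
    """Seeded 20-gene x 9-sample dataset with arbitrary positive signals."""
    rng = np.random.default_rng(42)
    samples = list(group_map)
    signal = rng.lognormal(5.0, 1.0, size=(20, 9))
    call = rng.choice(np.array(["P", "M", "A"], dtype=object), size=(20, 9))
    return ExpressionDataset(
        gene_ids=[f"g{i:02d}" for i in range(20)],
        sample_ids=samples,
        group_of_sample=group_map,
        signal=signal,
        call=call,
    )
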