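"""Principal-component QC of replicate expression profiles.

Each sample (one animal's expression profile) is projected onto the leading
principal axes of the gene-centered signal matrix; on well-behaved bilateral
injury data the samples cluster by injury status (ipsilateral, contralateral,
naive). Scores and per-component variance fractions are the QC output —
no gene selection depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ConfigurationError, ExpressionDataset


@dataclass
class PCAResult:
    """Sample scores and variance fractions from an SVD of centered signals."""

    scores: np.ndarray  # samples x components
    variance_fraction: np.ndarray  # per retained component
    n_components: int
    sample_ids: list[str]


def pca_scores(
    dataset: ExpressionDataset,
    n_components: int = 3,
    log2: bool = True,
    pseudocount: float = 1.0,
) -> PCAResult:
    """Project samples onto the leading principal components.

    Signals are log2-transformed by default (``log2(signal + pseudocount)``;
    microarray signals are positive and right-skewed), then each gene is
    mean-centered across samples. The SVD of the centered samples x genes
    matrix gives scores ``U @ diag(s)`` and variance fractions
    ``s_k^2 / sum(s^2)``. Component signs are fixed by making the
    largest-magnitude gene loading of each component positive, so output is
    deterministic and invariant to sample order (up to row permutation).

    A constant matrix has zero total variance; all fractions are returned as
    zero rather than NaN.
    """
    if dataset.n_samples < 2:
        raise ConfigurationError("PCA requires at least 2 samples")
    max_rank = min(dataset.n_genes, dataset.n_samples)
    if not 1 <= n_components <= max_rank:
        raise ConfigurationError(
            f"n_components must be in [1, {max_rank}], got {n_components}"
        )

    x = dataset.signal.astype(float)
    if log2:
        x = np.log2(x + pseudocount)
    x = x - x.mean(axis=1, keepdims=True)  # gene-wise centering
    # samples are observations: rows of x.T
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)

    # deterministic sign: largest-|loading| positive per component
    for k in range(len(s)):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0

    total = float(np.sum(s**2))
    if total > 0:
        fractions = (s**2) / total
    else:
        fractions = np.zeros_like(s)

    return PCAResult(
        scores=u[:, :n_components] * s[:n_components],
        variance_fraction=fractions[:n_components],
        n_components=n_components,
        sample_ids=list(dataset.sample_ids),
    )
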