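"""Centered PCA for qualitative exploration of the spectrum table."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class PCAResult:
    loadings: np.ndarray  # components x variables
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_fit(X: np.ndarray, n_components: int) -> PCAResult:
    """PCA of column-centered ``X``; components ordered by explained variance.

    ``n_components`` beyond the matrix rank is reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds data rank {rank}; reducing",
            stacklevel=2,
        )
        n_components = rank
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(
        loadings=model.components_,
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        mean=model.mean_,
    )
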