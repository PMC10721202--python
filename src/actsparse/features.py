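"""PCA reduction of per-layer activation matrices and predictor z-scoring.

Layer activation matrices are far too wide to regress on directly (the
first convolution layer alone has 3,211,264 units), so each layer is
reduced by a column-centered PCA, retaining the smallest leading set of
components whose cumulative explained variance reaches a target
fraction (default 0.80).  Principal-component signs are made
reproducible by forcing the largest-magnitude loading of each component
to be positive.  PC scores and sparsity predictors are z-scored
(sample-SD, n-1 denominator) before entering any regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, DomainError

__all__ = ["FeatureMatrix", "pca_retain", "first_k_scores", "zscore_columns"]


@dataclass
class FeatureMatrix:
    """PC scores of one layer with its explained-variance ledger.

    ``scores`` holds the retained ``k`` components only; ``k`` is the
    smallest integer whose cumulative explained-variance fraction
    reaches ``variance_target``.  ``explained_fraction`` covers the full
    computed spectrum (all min(n_images - 1, d) components), so its sum
    is 1 for centered data.
    """

    layer_id: str
    scores: np.ndarray  # (n_images, k)
    explained_fraction: np.ndarray  # full spectrum, non-increasing, sums to 1
    k: int
    variance_target: float
    components: np.ndarray | None = None  # (n_components_computed, d) loadings
    mean: np.ndarray | None = None  # column means used for centering

    @property
    def n_images(self) -> int:
        return self.scores.shape[0]


def pca_retain(
    activations: np.ndarray,
    variance_target: float = 0.80,
    layer_id: str = "",
    keep_all_scores: bool = False,
) -> FeatureMatrix:
    """Column-centered PCA keeping components up to a variance target.

    Parameters
    ----------
    activations
        (n_images, d) matrix, n_images >= 3.  Columns are centered but
        not scaled; z-scoring is applied to PC scores downstream.
    variance_target
        Fraction in (0, 1]; ``k`` is the smallest component count whose
        cumulative explained-variance fraction reaches it.
    keep_all_scores
        If True, ``scores`` holds the full computed spectrum instead of
        the retained ``k`` columns (``k`` is unchanged); used when a
        caller later slices a fixed number of leading components.
    """
    X = np.asarray(activations, dtype=np.float64)
    if X.ndim != 2:
        raise DomainError("activations must be a 2-D (n_images, d) matrix")
    n, d = X.shape
    if n < 3:
        raise DomainError(f"PCA needs at least 3 images, got {n}")
    if not 0.0 < variance_target <= 1.0:
        raise DomainError(f"variance_target must be in (0, 1], got {variance_target}")
    if not np.any(np.std(X, axis=0) > 0):
        raise DegenerateInputError(
            f"layer {layer_id or '<unnamed>'}: constant activation matrix, "
            "PCA is undefined"
        )
    n_comp = min(n - 1, d)
    pca = PCA(n_components=n_comp, svd_solver="full" if min(n, d) < 1000 else "auto",
              random_state=0)
    scores = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_.copy()
    components = pca.components_.copy()

    # Fix component signs: largest-|loading| entry of each component positive.
    for j in range(n_comp):
        pivot = np.argmax(np.abs(components[j]))
        if components[j, pivot] < 0:
            components[j] *= -1.0
            scores[:, j] *= -1.0

    # Drop numerically-null trailing components from the retention rule.
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, n_comp)
    return FeatureMatrix(
        layer_id=layer_id,
        scores=scores if keep_all_scores else scores[:, :k],
        explained_fraction=frac,
        k=k,
        variance_target=variance_target,
        components=components,
        mean=pca.mean_.copy(),
    )


def first_k_scores(fm: FeatureMatrix, k: int) -> np.ndarray:
    """Leading-``k`` PC score columns, in eigenvalue order.

    ``k`` may not exceed the number of score columns the matrix holds
    (the retained count ``fm.k``, or the full spectrum when it was kept);
    ``k = 0`` returns an empty (n_images, 0) matrix.
    """
    if k < 0 or k > fm.scores.shape[1]:
        raise DomainError(
            f"requested k={k} but layer {fm.layer_id!r} holds "
            f"{fm.scores.shape[1]} score columns (retained k={fm.k})"
        )
    return fm.scores[:, :k]


def zscore_columns(X: np.ndarray, labels: list[str] | None = None) -> np.ndarray:
    """Z-transform each column to mean 0 and sample SD 1 (n-1 denominator).

    Raises :class:`DegenerateInputError` naming the offending column if
    any column is constant.
    """
    X = np.asarray(X, dtype=np.float64)
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        name = labels[dead[0]] if labels else f"column {dead[0]}"
        raise DegenerateInputError(f"constant predictor ({name}): cannot z-score")
    Z = (X - mean) / sd
    return Z[:, 0] if one_d else Z
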