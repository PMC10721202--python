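"""Sparsity metrics for non-negative activation vectors.

The sparsity of a neural code measures the inequity of its activation
distribution: a sparse code has few strongly active units and many
near-silent ones.  The primary metric is the Gini index

    G = sum_i (2 i - n - 1) x_i / (n sum_i x_i),

with the activations ``x_i`` sorted in ascending order and ``i``
1-based.  G is 0 for a perfectly uniform code and (n-1)/n for a
one-hot code.  Among common sparsity statistics the Gini index is the
one that satisfies the full set of inequity axioms (scale invariance,
Dalton/Robin-Hood transfer monotonicity, increase under added zeros,
cloning invariance); kurtosis and the L1 norm each fail at least one.

An equivalent "pairwise" form, G = sum_ij |x_i - x_j| / (2 n^2 mean),
needs no sorting and serves here as an independent verification oracle.

The Treves-Rolls sparseness, popular in neurophysiology, is provided as
an alternate metric: S = 1 - (mean x)^2 / (mean x^2).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedSparsityError

__all__ = [
    "gini_index",
    "gini_pairwise_oracle",
    "treves_rolls_sparseness",
    "sparsity_profile",
    "METRICS",
]


def _validate(x) -> np.ndarray:
    """Check the post-ReLU activation-vector contract and return float64."""
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise DomainError(f"sparsity needs at least 2 activations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise DomainError("activation vector contains non-finite values")
    if np.any(arr < 0):
        raise DomainError("negative activation violates the post-ReLU contract")
    if not np.any(arr > 0):
        raise UndefinedSparsityError(
            "all-zero activation vector: sparsity is undefined"
        )
    return arr


def gini_index(x) -> float:
    """Gini index of a non-negative activation vector.

    Parameters
    ----------
    x
        1-D array-like of finite, non-negative activations, length >= 2,
        with at least one positive entry.  Higher-dimensional input is
        flattened.

    Returns
    -------
    float
        Gini index in [0, (n-1)/n].

    Raises
    ------
    DomainError
        Negative or non-finite entries, or fewer than 2 entries.
    UndefinedSparsityError
        All entries are zero.
    """
    arr = np.sort(_validate(x))
    arr /= arr[-1]  # scale-invariant; guards against under/overflow of sums
    n = arr.size
    # numpy's pairwise summation keeps both accumulations accurate for
    # vectors of several million entries (first conv layer: 3,211,264).
    i = np.arange(1, n + 1, dtype=np.float64)
    return float(((2.0 * i - n - 1.0) @ arr) / (n * arr.sum()))


def gini_pairwise_oracle(x, *, chunk: int = 2048) -> float:
    """Gini index via exhaustive pairwise absolute differences.

    Computes sum_ij |x_i - x_j| / (2 n^2 mean) by enumerating every
    ordered pair, with no sorting.  O(n^2); intended as an independent
    check of :func:`gini_index`, not for production-size vectors.
    """
    arr = _validate(x)
    arr = arr / arr.max()  # scale-invariant; avoids extreme-magnitude sums
    n = arr.size
    total = 0.0
    for start in range(0, n, chunk):
        block = arr[start : start + chunk]
        total += np.abs(block[:, None] - arr[None, :]).sum()
    return float(total / (2.0 * n * n * arr.mean()))


def treves_rolls_sparseness(x) -> float:
    """Treves-Rolls sparseness S = 1 - (mean x)^2 / (mean x^2).

    The activity ratio a = (mean)^2 / (mean of squares) equals 1 for a
    constant code and 1/n for a one-hot code, so S lies in [0, 1 - 1/n].
    The raw 1 - a form is reported (not the (1-a)/(1-1/n) normalization);
    the metric name travels with every output table so the convention is
    auditable.
    """
    arr = _validate(x)
    arr = arr / arr.max()  # scale-invariant; avoids squared-term underflow
    mean = arr.mean()
    mean_sq = (arr * arr).mean()
    return float(1.0 - mean * mean / mean_sq)


METRICS = {
    "gini": gini_index,
    "treves_rolls": treves_rolls_sparseness,
}


def sparsity_profile(
    activations: Sequence[Mapping[str, np.ndarray]],
    metric: str = "gini",
    layers: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-image, per-layer sparsity table.

    Parameters
    ----------
    activations
        One mapping per image, layer_id -> flattened activation vector.
    metric
        ``"gini"`` or ``"treves_rolls"``.
    layers
        Column order; defaults to the key order of the first image.

    Returns
    -------
    pandas.DataFrame
        n_images x n_layers matrix of sparsity values; ``df.attrs["metric"]``
        records the metric used.
    """
    if metric not in METRICS:
        raise DomainError(f"unknown sparsity metric {metric!r}")
    fn = METRICS[metric]
    if not activations:
        raise DomainError("no activations supplied")
    cols = list(layers) if layers is not None else list(activations[0].keys())
    rows = []
    for img in activations:
        missing = [c for c in cols if c not in img]
        if missing:
            raise DomainError(f"image is missing layers {missing}")
        rows.append([fn(img[c]) for c in cols])
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["metric"] = metric
    return df
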