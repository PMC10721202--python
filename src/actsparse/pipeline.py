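"""End-to-end helpers wiring images through the encoder to the battery."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .encoder import EncoderBackend, extract_layer_activations, preprocess_image
from .features import FeatureMatrix, pca_retain
from .regression import BatteryResult, CVConfig, run_model_battery
from .sparsity import sparsity_profile

__all__ = [
    "encode_images",
    "activation_matrices",
    "compute_sparsity_profile",
    "reduce_layers",
    "run_pipeline",
]


def encode_images(
    images: Iterable, backend: EncoderBackend, layers: list[str] | None = None
) -> list[dict[str, np.ndarray]]:
    """Preprocess and forward each image; one layer->vector map per image."""
    out = []
    for src in images:
        x = preprocess_image(src, backend)
        out.append(extract_layer_activations(x, backend, layers))
    return out


def activation_matrices(
    activations: Sequence[dict[str, np.ndarray]]
) -> dict[str, np.ndarray]:
    """Stack per-image vectors into per-layer (n_images, d) matrices."""
    layers = list(activations[0].keys())
    return {l: np.stack([img[l] for img in activations]) for l in layers}


def compute_sparsity_profile(
    images: Iterable,
    backend: EncoderBackend,
    metric: str = "gini",
    layers: list[str] | None = None,
) -> pd.DataFrame:
    """Images -> n_images x n_layers sparsity table in one call."""
    return sparsity_profile(encode_images(images, backend, layers), metric)


def reduce_layers(
    mats: dict[str, np.ndarray], variance_target: float = 0.80
) -> dict[str, FeatureMatrix]:
    """One PCA per layer at the given explained-variance target.

    The full computed spectrum is kept in ``scores`` (the retained
    count ``k`` still follows the variance rule) so the global models
    can slice a fixed number of leading components even for layers
    whose retained count is small.
    """
    return {l: pca_retain(A, variance_target, layer_id=l, keep_all_scores=True)
            for l, A in mats.items()}


def run_pipeline(
    images: Iterable,
    scores: np.ndarray,
    backend: EncoderBackend,
    cfg: CVConfig,
    metric: str = "gini",
    variance_target: float = 0.80,
    permute_univariate: bool = True,
) -> tuple[pd.DataFrame, BatteryResult]:
    """Full analysis: encode, measure sparsity, reduce, fit the battery.

    Returns the sparsity table and the battery result.  With
    ``cfg.preprocess == "fold"`` the raw activation matrices are handed
    to the battery so PCA/z-scoring refit inside training folds.
    """
    acts = encode_images(images, backend)
    profile = sparsity_profile(acts, metric)
    mats = activation_matrices(acts)
    features = None if cfg.preprocess == "fold" else reduce_layers(
        mats, variance_target)
    battery = run_model_battery(
        profile, features, np.asarray(scores, dtype=np.float64), cfg,
        activations=mats if cfg.preprocess == "fold" else None,
        permute_univariate=permute_univariate,
    )
    return profile, battery
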