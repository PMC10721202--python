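"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Three generators make every pipeline stage testable without external
image datasets or pretrained weights:

* activation tensors with controllable sparsity — per-image, per-layer
  Gamma(k, 1) draws.  The Gamma family is used because its population
  Gini index has a closed form, G(k) = Gamma(k + 1/2) / (Gamma(k + 1)
  sqrt(pi)), giving analytic anchors (k = 1, the exponential case,
  gives exactly 0.5) that do not depend on the code under test.
  Smaller shape k means a more unequal (sparser) code.  A per-image
  latent factor shared across layers induces the correlated layer
  sparsities seen in real encoders; the coupling strength is a knob.
* rating scores from a known linear model — y* = S beta + eps on
  z-scored sparsities, affinely mapped to the [0, 5] rating scale
  (affine, not clipped, so the linear generative model survives the
  mapping and parameter recovery stays interpretable).  The noise SD
  can be set directly or derived from a target population R2 via
  R2 = Var(S beta) / (Var(S beta) + sigma^2).
* 32x32 RGB images for the fixture encoder — "sparse_dots" (few bright
  Gaussian blobs on black, driving sparse early-layer codes) vs
  "dense_noise" (full-field uniform noise).

All outputs are bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.special import gammaln

from .errors import ConfigurationError

__all__ = [
    "SyntheticConfig",
    "generate_activations",
    "simulate_scores",
    "generate_fixture_images",
    "gamma_population_gini",
]


def gamma_population_gini(shape: float) -> float:
    """Closed-form Gini index of the Gamma(shape, scale) distribution.

    Scale-free; equals 0.5 at shape 1 (exponential) and decreases
    toward 0 as the shape grows.
    """
    return float(np.exp(gammaln(shape + 0.5) - gammaln(shape + 1.0)
                        - 0.5 * np.log(np.pi)))


@dataclass
class SyntheticConfig:
    """Ground-truth configuration for the synthetic study.

    ``beta`` holds the true per-layer effect of sparsity on the score,
    in score units per SD of sparsity.  Exactly one of ``noise_sd`` /
    ``target_r2`` must be set; ``target_r2`` derives the noise SD from
    the population-R2 identity.  ``gamma_shape_range`` bounds the
    per-image Gamma shape (smaller -> sparser); ``layer_coupling`` in
    [0, 1] sets how strongly the per-image latent sparsity factor is
    shared across layers (0 = independent layers, 1 = one factor).
    """

    n_images: int
    n_layers: int
    layer_sizes: list[int]
    beta: np.ndarray
    noise_sd: float | None = None
    target_r2: float | None = None
    gamma_shape_range: tuple[float, float] = (0.3, 5.0)
    layer_coupling: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.beta.size != self.n_layers:
            raise ConfigurationError(
                f"beta has {self.beta.size} entries for {self.n_layers} layers")
        if len(self.layer_sizes) != self.n_layers:
            raise ConfigurationError("layer_sizes length must equal n_layers")
        if any(s < 2 for s in self.layer_sizes):
            raise ConfigurationError("every layer size must be >= 2")
        if (self.noise_sd is None) == (self.target_r2 is None):
            raise ConfigurationError(
                "set exactly one of noise_sd / target_r2")
        if self.target_r2 is not None and not 0.0 < self.target_r2 < 1.0:
            raise ConfigurationError(f"target_r2 must be in (0,1), "
                                     f"got {self.target_r2}")
        lo, hi = self.gamma_shape_range
        if not (0.0 < lo <= hi):
            raise ConfigurationError(
                f"invalid gamma_shape_range {self.gamma_shape_range}")
        if not 0.0 <= self.layer_coupling <= 1.0:
            raise ConfigurationError("layer_coupling must be in [0, 1]")

    @property
    def layer_ids(self) -> list[str]:
        return [f"layer_{i + 1}" for i in range(self.n_layers)]


def generate_activations(cfg: SyntheticConfig) -> list[dict[str, np.ndarray]]:
    """Draw per-image, per-layer non-negative activation vectors.

    For image i and layer l the activations are Gamma(k_il, 1) with
    shape k_il interpolated across ``gamma_shape_range`` by a mixture
    of a per-image latent factor and per-layer independent noise
    (``layer_coupling`` sets the mixture weight).  Fully seeded.
    """
    rng = np.random.default_rng([cfg.seed, 17])
    lo, hi = cfg.gamma_shape_range
    out: list[dict[str, np.ndarray]] = []
    for _ in range(cfg.n_images):
        u = rng.uniform()  # shared latent sparsity level of this image
        img: dict[str, np.ndarray] = {}
        for lid, size in zip(cfg.layer_ids, cfg.layer_sizes):
            v = rng.uniform()
            w = cfg.layer_coupling * u + (1.0 - cfg.layer_coupling) * v
            shape = lo + w * (hi - lo)
            img[lid] = rng.gamma(shape, 1.0, size=size)
        out.append(img)
    return out


def simulate_scores(
    S: np.ndarray, cfg: SyntheticConfig
) -> tuple[np.ndarray, dict]:
    """Scores on [0, 5] from the linear model y* = S beta + eps.

    ``S`` must be the z-scored n x L sparsity matrix.  When
    ``cfg.target_r2`` is set the noise SD is
    sqrt(Var(S beta) (1 - R2) / R2).  y* is affinely mapped onto
    [0, 5]; the map and realized noise SD are returned in ``info`` so
    recovered coefficients can be placed back on the raw-score scale.
    """
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[1] != cfg.n_layers:
        raise ConfigurationError(
            f"S must be (n_images, {cfg.n_layers}), got {S.shape}")
    if np.max(np.abs(S.mean(axis=0))) > 1e-6:
        raise ConfigurationError("S must be z-scored (column means not ~0)")
    rng = np.random.default_rng([cfg.seed, 19])
    signal = S @ cfg.beta
    if cfg.target_r2 is not None:
        var_signal = float(np.var(signal, ddof=1))
        if var_signal == 0.0:
            raise ConfigurationError(
                "target_r2 requires a non-degenerate signal (beta != 0)")
        noise_sd = float(np.sqrt(var_signal * (1.0 - cfg.target_r2)
                                 / cfg.target_r2))
    else:
        noise_sd = float(cfg.noise_sd)
    y_star = signal + rng.normal(0.0, noise_sd, size=S.shape[0])
    lo, hi = float(y_star.min()), float(y_star.max())
    if hi == lo:  # degenerate: constant scores (beta = 0, noise_sd = 0)
        scores = np.full(S.shape[0], 2.5)
        scale, offset = 1.0, 2.5 - lo
    else:
        scale = 5.0 / (hi - lo)
        offset = -lo * scale
        scores = y_star * scale + offset
    info = {
        "noise_sd": noise_sd,
        "affine_scale": scale,
        "affine_offset": offset,
        "signal_variance": float(np.var(signal, ddof=1)),
        "beta": cfg.beta.tolist(),
        "seed": cfg.seed,
    }
    return scores, info


def generate_fixture_images(
    n: int,
    sparsity_class: str,
    seed: int = 0,
    out_dir: str | Path | None = None,
    size: int = 32,
) -> list[np.ndarray] | list[Path]:
    """Seeded 32x32 RGB stimuli in two sparsity classes.

    ``sparse_dots``: black field with 2-4 bright Gaussian blobs — a
    stimulus whose early convolutional code is highly unequal.
    ``dense_noise``: full-field uniform noise — a dense, equal code.
    Returns uint8 arrays, or PNG paths when ``out_dir`` is given.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if sparsity_class not in ("sparse_dots", "dense_noise"):
        raise ConfigurationError(
            f"unknown sparsity_class {sparsity_class!r}")
    class_key = {"sparse_dots": 1, "dense_noise": 2}[sparsity_class]
    rng = np.random.default_rng([seed, 23, class_key])
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    images: list[np.ndarray] = []
    for _ in range(n):
        if sparsity_class == "dense_noise":
            img = rng.uniform(0, 255, size=(size, size, 3))
        else:
            field = np.zeros((size, size))
            for _ in range(rng.integers(2, 5)):
                cy, cx = rng.uniform(4, size - 4, size=2)
                sigma = rng.uniform(1.0, 2.0)
                amp = rng.uniform(180, 255)
                field += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                                      / (2 * sigma ** 2))
            img = np.clip(field, 0, 255)[:, :, None].repeat(3, axis=2)
        images.append(img.astype(np.uint8))
    if out_dir is None:
        return images
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        p = out_dir / f"{sparsity_class}_{i:04d}.png"
        Image.fromarray(img).save(p)
        paths.append(p)
    return paths
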