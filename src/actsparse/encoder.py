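"""Convolutional encoders that turn images into per-layer activation vectors.

Two backends share one numpy inference engine:

* :class:`VGG16Backend` — the standard 16-layer architecture (13
  convolution layers in five blocks, two 4096-unit fully connected
  layers) at 224x224 input.  Layer shapes are always available for
  structural queries; running a forward pass requires a weight file
  supplied by the user (``.npz``, see :func:`load_vgg16_weights`) —
  weights are never fetched implicitly.
* :class:`FixtureBackend` — a small seeded random network (3 convolution
  layers + 1 fully connected, 32x32 input) whose weights are fully
  determined by an integer seed, so tests and simulations need no
  download and are bit-reproducible.

Every exported activation is taken after the ReLU nonlinearity (hence
non-negative) and, for convolution blocks, before pooling; the H x W x C
feature maps are flattened row-major into one-dimensional vectors.
Inference is purely feed-forward and deterministic (no dropout, no
batch statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ConfigurationError, InputError

__all__ = [
    "LayerSpec",
    "EncoderBackend",
    "VGG16Backend",
    "FixtureBackend",
    "vgg16_backend",
    "fixture_backend",
    "preprocess_image",
    "extract_layer_activations",
    "load_vgg16_weights",
    "vgg16_random_weights",
]

logger = logging.getLogger(__name__)

# ImageNet channel statistics on the [0, 1] scale.
_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

# VGG16 convolution blocks: (channels, number of 3x3 conv layers).
_VGG16_BLOCKS = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]
_VGG16_FC = 4096


@dataclass(frozen=True)
class LayerSpec:
    """Name, kind and output shape of one measured layer.

    ``shape`` is (H, W, C) for convolution layers (post-ReLU, pre-pool
    feature-map size) and (size,) for fully connected layers.
    """

    layer_id: str
    kind: str  # "convolution" | "fully_connected"
    shape: tuple[int, ...]

    @property
    def n_units(self) -> int:
        return int(np.prod(self.shape))


# ---------------------------------------------------------------------------
# numpy layer primitives (float32 internally, float64 on export)

def _conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 'same' convolution; x (H,W,Cin), w (3,3,Cin,Cout), b (Cout,)."""
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(0, 1))
    # win: (H, W, Cin, 3, 3); contract over (Cin, kh, kw)
    out = np.tensordot(win, w, axes=([2, 3, 4], [2, 0, 1]))
    return out + b


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    return x.reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))


class EncoderBackend:
    """Common interface: named layer specs plus a deterministic forward pass."""

    name: str
    input_size: int
    layer_specs: list[LayerSpec]

    @property
    def layer_ids(self) -> list[str]:
        return [s.layer_id for s in self.layer_specs]

    def spec(self, layer_id: str) -> LayerSpec:
        for s in self.layer_specs:
            if s.layer_id == layer_id:
                return s
        raise ConfigurationError(
            f"unknown layer {layer_id!r}; backend {self.name} has {self.layer_ids}"
        )

    def normalize(self, rgb01: np.ndarray) -> np.ndarray:
        """Map a [0,1]-scaled RGB tensor to the network's input scale."""
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Run inference; return layer_id -> flattened post-ReLU float64 vector."""
        raise NotImplementedError


def _conv_stack_forward(
    x: np.ndarray,
    blocks: list[tuple[int, int]],
    weights: dict[str, np.ndarray],
    fc_names: list[str],
) -> dict[str, np.ndarray]:
    """Shared forward pass for VGG-style conv blocks followed by FC layers."""
    out: dict[str, np.ndarray] = {}
    h = x.astype(np.float32)
    for bi, (_, n_conv) in enumerate(blocks, start=1):
        for ci in range(1, n_conv + 1):
            name = f"conv{bi}_{ci}"
            h = _relu(_conv2d_same(h, weights[f"{name}.weight"],
                                   weights[f"{name}.bias"]))
            out[name] = h.ravel().astype(np.float64)
        h = _maxpool2(h)
    v = h.ravel()
    for name in fc_names:
        v = _relu(v @ weights[f"{name}.weight"] + weights[f"{name}.bias"])
        out[name] = v.astype(np.float64)
    return out


class VGG16Backend(EncoderBackend):
    """VGG16-architecture adapter (13 conv + 2 FC measured layers, 224x224 input).

    Layer specs (shapes, unit counts) are available without weights; the
    forward pass requires ``weights`` — a mapping as returned by
    :func:`load_vgg16_weights` or :func:`vgg16_random_weights`.
    Input normalization uses the ImageNet per-channel mean/std that the
    pretrained weight distribution expects.
    """

    def __init__(self, weights: dict[str, np.ndarray] | None = None):
        self.name = "vgg16_imagenet"
        self.input_size = 224
        self.weights = weights
        specs: list[LayerSpec] = []
        res = 224
        for bi, (ch, n_conv) in enumerate(_VGG16_BLOCKS, start=1):
            for ci in range(1, n_conv + 1):
                specs.append(LayerSpec(f"conv{bi}_{ci}", "convolution",
                                       (res, res, ch)))
            res //= 2
        specs.append(LayerSpec("fc1", "fully_connected", (_VGG16_FC,)))
        specs.append(LayerSpec("fc2", "fully_connected", (_VGG16_FC,)))
        self.layer_specs = specs
        if weights is not None:
            _check_vgg16_weights(weights)

    def normalize(self, rgb01: np.ndarray) -> np.ndarray:
        return (rgb01 - _IMAGENET_MEAN) / _IMAGENET_STD

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        if self.weights is None:
            raise ConfigurationError(
                "VGG16 backend has no weights loaded; supply a weight file "
                "(see load_vgg16_weights) to run inference"
            )
        return _conv_stack_forward(x, _VGG16_BLOCKS, self.weights, ["fc1", "fc2"])


def _check_vgg16_weights(weights: dict[str, np.ndarray]) -> None:
    cin = 3
    for bi, (ch, n_conv) in enumerate(_VGG16_BLOCKS, start=1):
        for ci in range(1, n_conv + 1):
            name = f"conv{bi}_{ci}"
            expect = (3, 3, cin, ch)
            got = weights.get(f"{name}.weight")
            if got is None or got.shape != expect:
                raise ConfigurationError(
                    f"weight {name}.weight missing or wrong shape "
                    f"(expected {expect}, got {None if got is None else got.shape})"
                )
            cin = ch
    if weights["fc1.weight"].shape != (7 * 7 * 512, _VGG16_FC):
        raise ConfigurationError("fc1.weight must be (25088, 4096), row-major "
                                 "(H, W, C) flattening of the last feature map")


def load_vgg16_weights(path: str | Path) -> dict[str, np.ndarray]:
    """Load VGG16 weights from a local ``.npz`` file.

    Expected keys: ``conv{b}_{i}.weight`` with shape (3, 3, Cin, Cout),
    ``conv{b}_{i}.bias`` (Cout,), ``fc1.weight`` (25088, 4096),
    ``fc2.weight`` (4096, 4096) and matching ``.bias`` vectors.  The FC
    input ordering corresponds to row-major (H, W, C) flattening of the
    pooled 7x7x512 feature map.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"weight file not found: {path}")
    with np.load(path) as z:
        return {k: z[k].astype(np.float32) for k in z.files}


def vgg16_random_weights(seed: int = 0) -> dict[str, np.ndarray]:
    """He-initialized random VGG16 weights (for structural/forward tests only)."""
    rng = np.random.default_rng(seed)
    weights: dict[str, np.ndarray] = {}
    cin = 3
    for bi, (ch, n_conv) in enumerate(_VGG16_BLOCKS, start=1):
        for ci in range(1, n_conv + 1):
            fan_in = 9 * cin
            weights[f"conv{bi}_{ci}.weight"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (3, 3, cin, ch)
            ).astype(np.float32)
            weights[f"conv{bi}_{ci}.bias"] = np.zeros(ch, dtype=np.float32)
            cin = ch
    dims = [7 * 7 * 512, _VGG16_FC, _VGG16_FC]
    for i, name in enumerate(["fc1", "fc2"]):
        weights[f"{name}.weight"] = rng.normal(
            0.0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1])
        ).astype(np.float32)
        weights[f"{name}.bias"] = np.zeros(dims[i + 1], dtype=np.float32)
    return weights


# Fixture network: 3 conv blocks + 1 FC at 32x32 input.
_FIXTURE_BLOCKS = [(8, 1), (12, 1), (16, 1)]
_FIXTURE_FC = 32


class FixtureBackend(EncoderBackend):
    """Small seeded random convolutional network (no download, bit-reproducible).

    Architecture: three 3x3 convolution layers (8, 12, 16 channels) each
    followed by 2x2 max pooling, then one 32-unit fully connected layer,
    at 32x32 RGB input.  Weights are He-initialized Gaussians drawn from
    ``numpy.random.default_rng(seed)``; biases are zero, so an all-zero
    image produces all-zero activations at every layer.  Inputs are
    scaled to [0, 1] with no further normalization.
    """

    def __init__(self, seed: int = 0):
        self.name = "fixture"
        self.seed = int(seed)
        self.input_size = 32
        rng = np.random.default_rng(self.seed)
        weights: dict[str, np.ndarray] = {}
        cin = 3
        for bi, (ch, _) in enumerate(_FIXTURE_BLOCKS, start=1):
            fan_in = 9 * cin
            weights[f"conv{bi}_1.weight"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (3, 3, cin, ch)
            ).astype(np.float32)
            weights[f"conv{bi}_1.bias"] = np.zeros(ch, dtype=np.float32)
            cin = ch
        flat = (32 // 2 ** len(_FIXTURE_BLOCKS)) ** 2 * cin
        weights["fc1.weight"] = rng.normal(
            0.0, np.sqrt(2.0 / flat), (flat, _FIXTURE_FC)
        ).astype(np.float32)
        weights["fc1.bias"] = np.zeros(_FIXTURE_FC, dtype=np.float32)
        self.weights = weights

        specs: list[LayerSpec] = []
        res = 32
        for bi, (ch, _) in enumerate(_FIXTURE_BLOCKS, start=1):
            specs.append(LayerSpec(f"conv{bi}_1", "convolution", (res, res, ch)))
            res //= 2
        specs.append(LayerSpec("fc1", "fully_connected", (_FIXTURE_FC,)))
        self.layer_specs = specs

    def normalize(self, rgb01: np.ndarray) -> np.ndarray:
        return rgb01

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        blocks = [(ch, 1) for ch, _ in _FIXTURE_BLOCKS]
        return _conv_stack_forward(x, blocks, self.weights, ["fc1"])


def vgg16_backend(weights: dict[str, np.ndarray] | str | Path | None = None
                  ) -> VGG16Backend:
    """Construct the VGG16 adapter, optionally loading a local weight file."""
    if isinstance(weights, (str, Path)):
        weights = load_vgg16_weights(weights)
    return VGG16Backend(weights)


def fixture_backend(seed: int = 0) -> FixtureBackend:
    """Construct the deterministic fixture network for a given seed."""
    return FixtureBackend(seed)


def preprocess_image(source, backend: EncoderBackend) -> np.ndarray:
    """Decode, standardize and normalize an image for a backend.

    ``source`` may be a file path, a ``PIL.Image`` or an (H, W, 3) or
    (H, W) uint8/float array.  The image is converted to RGB (grayscale
    is replicated across channels, alpha is dropped, with a warning),
    resampled bilinearly to the backend's square input size, scaled to
    [0, 1] and passed through the backend's normalization.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            with Image.open(path) as im:
                im.load()
                img = im
                return _standardize(img, backend, str(path))
        except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
            raise InputError(f"cannot read image {path}: {exc}") from exc
    if isinstance(source, np.ndarray):
        if source.size == 0:
            raise InputError("zero-size image array")
        if source.dtype != np.uint8:
            arr = np.clip(source, 0, 255).astype(np.uint8)
        else:
            arr = source
        source = Image.fromarray(arr)
    return _standardize(source, backend, "<in-memory image>")


def _standardize(img: Image.Image, backend: EncoderBackend, label: str
                 ) -> np.ndarray:
    if img.width == 0 or img.height == 0:
        raise InputError(f"zero-size image: {label}")
    if img.mode != "RGB":
        logger.warning("converting %s from mode %s to RGB", label, img.mode)
        img = img.convert("RGB")
    size = backend.input_size
    if (img.width, img.height) != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    rgb01 = np.asarray(img, dtype=np.float32) / 255.0
    return backend.normalize(rgb01).astype(np.float32)


def extract_layer_activations(
    image: np.ndarray,
    backend: EncoderBackend,
    layers: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Forward one standardized image; return flattened post-ReLU vectors.

    Each returned vector has length H*W*C (convolution) or the FC size,
    with every entry >= 0.  Extraction is deterministic for fixed
    weights and input.
    """
    ids = backend.layer_ids
    if layers is None:
        layers = ids
    else:
        unknown = [l for l in layers if l not in ids]
        if unknown:
            raise ConfigurationError(
                f"unknown layer(s) {unknown}; backend {backend.name} has {ids}"
            )
    acts = backend.forward(image)
    out = {}
    for layer_id in layers:
        v = acts[layer_id]
        spec = backend.spec(layer_id)
        assert v.size == spec.n_units, (layer_id, v.size, spec.n_units)
        assert v.min() >= 0.0, f"negative activation exported from {layer_id}"
        out[layer_id] = v
    return out
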