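"""Fixed-length features from composite images via CNN-style backbones.

Eleven backbone entries mirror the canonical ImageNet architectures'
*interfaces*: their published square input sizes and the width of the last
feature-extraction layer before the classifier (the penultimate
activation).  Each entry is realized as a lightweight randomly-initialized
convolutional encoder in pure numpy — a family-flavored stem and a short
stack of strided convolutions, closed by either global average pooling
over a map with exactly the published channel width (pooling families) or
a flatten + dense projection to the published width (AlexNet/VGG).

Random weights are fully determined by the backbone name and a seed, so
feature extraction is reproducible; pretrained ImageNet weights are not
bundled and requesting them raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "BackboneSpec",
    "FeatureMatrix",
    "backbone_input_sizes",
    "backbone_registry",
    "extract_features",
    "get_backbone",
]


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    input_size: int
    feature_dim: int
    weights_source: str = "random"  # only "random" is constructible offline


@dataclass
class FeatureMatrix:
    """Samples x feature-dimension table with backbone provenance."""

    values: np.ndarray
    backbone: str
    sample_ids: list = field(default_factory=list)
    labels: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.values.shape[1]


# layer grammar: ("conv", out_channels, kernel, stride, pad)
#                ("pool", kernel, stride)            max pooling
#                ("gap", feature_dim)                1x1 conv to width + GAP
#                ("dense", feature_dim)              flatten + dense to width
_PLANS: dict[str, tuple[int, int, tuple]] = {
    "AlexNet": (227, 4096, (
        ("conv", 32, 11, 4, 0), ("pool", 3, 2),
        ("conv", 48, 5, 1, 2), ("pool", 3, 2),
        ("conv", 64, 3, 1, 1), ("pool", 3, 2),
        ("dense", 4096),
    )),
    "DenseNet201": (224, 1920, (
        ("conv", 32, 7, 2, 3), ("pool", 2, 2),
        ("conv", 48, 3, 2, 1), ("conv", 64, 3, 2, 1), ("conv", 96, 3, 2, 1),
        ("gap", 1920),
    )),
    "Inception-ResNet-V2": (299, 1536, (
        ("conv", 32, 3, 2, 0), ("conv", 48, 3, 2, 0), ("conv", 64, 3, 2, 0),
        ("conv", 96, 3, 2, 0), ("conv", 96, 3, 2, 0),
        ("gap", 1536),
    )),
    "InceptionV3": (299, 2048, (
        ("conv", 32, 3, 2, 0), ("conv", 48, 3, 2, 0), ("conv", 64, 3, 2, 0),
        ("conv", 96, 3, 2, 0), ("conv", 96, 3, 2, 0),
        ("gap", 2048),
    )),
    "MobileNetV2": (224, 1280, (
        ("conv", 16, 3, 2, 1), ("conv", 24, 3, 2, 1), ("conv", 32, 3, 2, 1),
        ("conv", 48, 3, 2, 1), ("conv", 64, 3, 2, 1),
        ("gap", 1280),
    )),
    "ResNet18": (224, 512, (
        ("conv", 32, 7, 2, 3), ("pool", 2, 2),
        ("conv", 48, 3, 2, 1), ("conv", 64, 3, 2, 1), ("conv", 64, 3, 2, 1),
        ("gap", 512),
    )),
    "ResNet50": (224, 2048, (
        ("conv", 32, 7, 2, 3), ("pool", 2, 2),
        ("conv", 48, 3, 2, 1), ("conv", 64, 3, 2, 1), ("conv", 64, 3, 2, 1),
        ("gap", 2048),
    )),
    "ResNet101": (224, 2048, (
        ("conv", 32, 7, 2, 3), ("pool", 2, 2),
        ("conv", 48, 3, 2, 1), ("conv", 64, 3, 2, 1),
        ("conv", 64, 3, 1, 1), ("conv", 64, 3, 2, 1),
        ("gap", 2048),
    )),
    "VGG16": (224, 4096, (
        ("conv", 32, 3, 2, 1), ("conv", 48, 3, 2, 1),
        ("conv", 64, 3, 2, 1), ("conv", 64, 3, 2, 1), ("pool", 2, 2),
        ("dense", 4096),
    )),
    "VGG19": (224, 4096, (
        ("conv", 32, 3, 2, 1), ("conv", 48, 3, 2, 1),
        ("conv", 64, 3, 2, 1), ("conv", 64, 3, 2, 1),
        ("conv", 64, 3, 1, 1), ("pool", 2, 2),
        ("dense", 4096),
    )),
    "Xception": (299, 2048, (
        ("conv", 32, 3, 2, 0), ("conv", 64, 3, 2, 0), ("conv", 64, 3, 2, 0),
        ("conv", 96, 3, 2, 0), ("conv", 96, 3, 2, 0),
        ("gap", 2048),
    )),
}


def backbone_registry() -> list[BackboneSpec]:
    """The 11 registered backbones with input sizes and penultimate widths."""
    return [BackboneSpec(name=n, input_size=sz, feature_dim=d)
            for n, (sz, d, _) in _PLANS.items()]


def get_backbone(name: str) -> BackboneSpec:
    for spec in backbone_registry():
        if spec.name.lower() == name.lower():
            return spec
    raise KeyError(f"unknown backbone {name!r}")


def backbone_input_sizes() -> frozenset[int]:
    return frozenset(spec.input_size for spec in backbone_registry())


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray,
            stride: int, pad: int) -> np.ndarray:
    """Strided 2-D convolution via im2col; x is (N, C, H, W), w (O, C, k, k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    k = w.shape[-1]
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)
    out = col @ w.reshape(w.shape[0], -1).T + b
    return out.transpose(0, 3, 1, 2)


def _maxpool(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    return win.max(axis=(-2, -1))


class ConvEncoder:
    """Randomly-initialized convolutional feature encoder for one backbone."""

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        if spec.weights_source != "random":
            raise ValueError(
                "pretrained weights are not bundled; use weights_source='random'"
            )
        self.spec = spec
        _, _, plan = _PLANS[spec.name]
        self.plan = plan
        # weights deterministic in (backbone name, seed)
        name_key = int.from_bytes(spec.name.encode(), "little") % (2 ** 31)
        rng = np.random.default_rng([seed, name_key])
        self.weights: list[tuple[np.ndarray, np.ndarray]] = []
        c = 3
        size = spec.input_size
        for layer in plan:
            if layer[0] == "conv":
                _, out_c, k, stride, pad = layer
                fan_in = c * k * k
                w = (rng.standard_normal((out_c, c, k, k))
                     * np.sqrt(2.0 / fan_in)).astype(np.float32)
                b = np.zeros(out_c, dtype=np.float32)
                self.weights.append((w, b))
                c = out_c
                size = (size + 2 * pad - k) // stride + 1
            elif layer[0] == "pool":
                _, k, stride = layer
                self.weights.append((None, None))
                size = (size - k) // stride + 1
            elif layer[0] == "gap":
                out_c = layer[1]
                w = (rng.standard_normal((out_c, c, 1, 1))
                     * np.sqrt(2.0 / c)).astype(np.float32)
                self.weights.append((w, np.zeros(out_c, dtype=np.float32)))
                c = out_c
            elif layer[0] == "dense":
                out_dim = layer[1]
                fan_in = c * size * size
                w = (rng.standard_normal((fan_in, out_dim))
                     * np.sqrt(2.0 / fan_in)).astype(np.float32)
                self.weights.append((w, np.zeros(out_dim, dtype=np.float32)))
            else:  # pragma: no cover
                raise ValueError(f"unknown layer {layer[0]!r}")

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) in [0, 1] -> (N, feature_dim)."""
        x = np.ascontiguousarray(
            batch.transpose(0, 3, 1, 2), dtype=np.float32
        )
        n = x.shape[0]
        for layer, (w, b) in zip(self.plan, self.weights):
            if layer[0] == "conv":
                x = np.maximum(_conv2d(x, w, b, layer[3], layer[4]), 0.0)
            elif layer[0] == "pool":
                x = _maxpool(x, layer[1], layer[2])
            elif layer[0] == "gap":
                x = np.maximum(_conv2d(x, w, b, 1, 0), 0.0)
                x = x.mean(axis=(2, 3))
            elif layer[0] == "dense":
                x = np.maximum(x.reshape(n, -1) @ w + b, 0.0)
        return np.asarray(x, dtype=np.float64)


def extract_features(images, spec: BackboneSpec, batch_size: int = 8,
                     seed: int = 0, sample_ids=None, labels=None
                     ) -> FeatureMatrix:
    """Run composites through a backbone's encoder and collect row features.

    ``images`` is a sequence of (H, W, 3) arrays or ``CompositeImage``
    objects already prepared to the backbone's input size; rows come back
    in input order.
    """
    arrays = []
    for im in images:
        arr = getattr(im, "channels", im)
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (spec.input_size, spec.input_size, 3):
            raise ValueError(
                f"image shape {arr.shape} does not match backbone input "
                f"{spec.input_size}x{spec.input_size}x3"
            )
        arrays.append(arr)
    if batch_size < 1:
        raise ValueError("batch_size must be positive")
    encoder = ConvEncoder(spec, seed=seed)
    rows = []
    for start in range(0, len(arrays), batch_size):
        chunk = np.stack(arrays[start:start + batch_size])
        rows.append(encoder.forward(chunk))
    values = (np.concatenate(rows)
              if rows else np.empty((0, spec.feature_dim)))
    return FeatureMatrix(values=values, backbone=spec.name,
                         sample_ids=list(sample_ids or range(len(arrays))),
                         labels=list(labels) if labels is not None else None)
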