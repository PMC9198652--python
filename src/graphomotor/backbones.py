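"""Frozen image-to-vector feature extractors ("backbones").

A backbone is any deterministic map from a rendered image to a
fixed-length vector (the transfer-learning feature-extraction paradigm:
weights trained on a source task stay frozen and the representations
are reused).  Two implementations are provided:

* :class:`RandomProjectionBackbone` — a seeded random projection of the
  downsampled grayscale pixels.  It has no semantic prior but is a
  deterministic, dependency-free linear image embedding, so geometric
  differences between traces (size, density, tremor texture) survive
  into the feature space.
* :class:`VGG16Backbone` — global-average-pooled activations of the
  last convolutional block of an ImageNet-pretrained VGG16 (512-d).
  Requires the optional torch/torchvision stack and a weight download;
  it raises a clear dependency error when unavailable.

Deep feature columns are named ``CNN:0000`` ... so they drop into the
same feature-table / evaluation path as the handcrafted battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .render import RenderedImage

__all__ = [
    "Backbone",
    "DeepFeatureVector",
    "RandomProjectionBackbone",
    "VGG16Backbone",
    "extract_deep_features",
    "deep_feature_names",
]


@dataclass
class DeepFeatureVector:
    values: np.ndarray
    backbone_id: str
    layer_id: str

    def __len__(self) -> int:
        return len(self.values)


class Backbone(Protocol):
    backbone_id: str
    layer_id: str

    def __call__(self, pixels: np.ndarray) -> np.ndarray: ...


@dataclass
class RandomProjectionBackbone:
    """Fixed-seed Gaussian random projection of 32x32 grayscale pixels.

    The projection matrix is derived from ``weight_seed`` only — it is
    part of the (frozen) model, independent of any cohort or evaluation
    seed, so identical images always map to identical vectors.
    """

    n_features: int = 512
    weight_seed: int = 20_220_530
    downsample: int = 32
    backbone_id: str = field(init=False)
    layer_id: str = "random_projection"

    def __post_init__(self) -> None:
        self.backbone_id = f"randproj-{self.n_features}-{self.weight_seed}"
        rng = np.random.default_rng(self.weight_seed)
        d = self.downsample * self.downsample
        self._w = rng.standard_normal((d, self.n_features)) / np.sqrt(d)

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        gray = np.asarray(pixels, dtype=float)
        if gray.ndim == 3:
            gray = gray.mean(axis=2)
        n = gray.shape[0]
        step = n // self.downsample
        blocks = gray[: step * self.downsample, : step * self.downsample]
        blocks = blocks.reshape(
            self.downsample, step, self.downsample, step
        ).mean(axis=(1, 3))
        vec = (1.0 - blocks).ravel() @ self._w  # trace-on-white -> signal
        return vec.astype(np.float64)


class VGG16Backbone:
    """Last-conv-block VGG16 features, global-average pooled to 512-d.

    Needs torch + torchvision with downloadable ImageNet weights.
    """

    backbone_id = "vgg16-imagenet"
    layer_id = "block5_conv3_gap"

    def __init__(self) -> None:
        try:
            import torch  # noqa: F401
            from torchvision.models import VGG16_Weights, vgg16
        except ImportError as exc:
            raise ImportError(
                "VGG16Backbone requires torch and torchvision "
                "(pip install torch torchvision); for an offline, "
                "dependency-free extractor use RandomProjectionBackbone"
            ) from exc
        import torch

        model = vgg16(weights=VGG16_Weights.IMAGENET1K_V1)
        self._features = model.features.eval()
        for p in self._features.parameters():
            p.requires_grad_(False)
        self._torch = torch

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        torch = self._torch
        mean = np.array([0.485, 0.456, 0.406])
        std = np.array([0.229, 0.224, 0.225])
        arr = (np.asarray(pixels, dtype=np.float32) - mean) / std
        x = torch.from_numpy(arr.transpose(2, 0, 1)[None].astype("float32"))
        with torch.no_grad():
            fmap = self._features(x)  # (1, 512, 7, 7)
        return fmap.mean(dim=(2, 3)).numpy().ravel().astype(np.float64)


def extract_deep_features(
    image: RenderedImage, backbone: Backbone | None = None
) -> DeepFeatureVector:
    """Apply a frozen backbone to one rendered image."""
    if backbone is None:
        backbone = RandomProjectionBackbone()
    values = np.asarray(backbone(image.pixels), dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("backbone produced non-finite features")
    return DeepFeatureVector(
        values=values, backbone_id=backbone.backbone_id,
        layer_id=backbone.layer_id,
    )


def deep_feature_names(n: int) -> list[str]:
    return [f"CNN:{i:04d}" for i in range(n)]
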