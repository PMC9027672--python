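"""Fixed-length feature vectors from segmented images.

Two extractors share one contract: given an image and its segmentation
label map they return a deterministic fixed-length real vector.

``extract_texture_stats`` is the built-in, dependency-light descriptor:
per-class region statistics (area fraction, mean, standard deviation,
intensity entropy) plus whole-image histogram moments.  It is the default
everywhere and requires nothing beyond numpy/scipy.

``extract_mobilenet`` adapts a pretrained MobileNetV2 (the 1280-wide
penultimate global-pooled activation) when torch/torchvision and a local
weights file are available.  It never downloads weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .phantoms import GrayImage

MOBILENET_V2_FEATURE_DIM = 1280


class FeatureError(ValueError):
    """Raised for mismatched inputs to a feature extractor."""


class MobileNetUnavailableError(RuntimeError):
    """torch/torchvision or local MobileNetV2 weights are missing.

    Use :func:`extract_texture_stats` instead, or install the ``mobilenet``
    extra and pass a local weights path.
    """


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    extractor_id: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise FeatureError(f"feature values must be 1-D, got shape {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise FeatureError("feature values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def dim(self) -> int:
        return int(self.values.size)


def _entropy(values: np.ndarray, levels: int) -> float:
    counts = np.bincount(values, minlength=levels)
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def extract_texture_stats(
    image: GrayImage, label_map: np.ndarray, n_classes: int | None = None
) -> FeatureVector:
    """Statistical texture descriptor over segmentation classes.

    For each of the ``n_classes`` segmentation classes: area fraction, mean
    intensity, intensity standard deviation, and Shannon entropy (bits) of
    the class's intensity histogram; empty classes contribute zeros.
    Appended are four whole-image histogram moments (mean, sd, skewness,
    excess kurtosis).  Dimension: ``4 * n_classes + 4``.
    """
    label_map = np.asarray(label_map)
    if label_map.shape != image.shape:
        raise FeatureError(
            f"label map shape {label_map.shape} does not match image {image.shape}"
        )
    if n_classes is None:
        n_classes = int(label_map.max()) + 1
    if label_map.min() < 0 or label_map.max() >= n_classes:
        raise FeatureError("label map values must lie in [0, n_classes - 1]")
    pixels = image.pixels
    total = pixels.size
    parts: list[float] = []
    for k in range(n_classes):
        region = pixels[label_map == k]
        if region.size == 0:
            parts.extend([0.0, 0.0, 0.0, 0.0])
            continue
        parts.extend(
            [
                region.size / total,
                float(region.mean()),
                float(region.std()),
                _entropy(region, image.levels),
            ]
        )
    flat = pixels.ravel().astype(float)
    sd = float(flat.std())
    if sd > 0:
        skew = float(sp_stats.skew(flat))
        kurt = float(sp_stats.kurtosis(flat))
    else:  # constant image: higher moments undefined, report 0
        skew, kurt = 0.0, 0.0
    parts.extend([float(flat.mean()), sd, skew, kurt])
    return FeatureVector(np.array(parts), extractor_id="texture_stats")


def extract_mobilenet(
    image: GrayImage,
    label_map: np.ndarray | None = None,
    weights_path: str | None = None,
) -> FeatureVector:
    """Penultimate-layer MobileNetV2 features of a (segmented) image.

    The grayscale image is replicated to 3 channels, bilinearly resized to
    224x224, normalized to [0, 1], and passed through MobileNetV2's
    convolutional trunk followed by global average pooling, yielding a
    1280-dimensional vector.  Weights must be a local torchvision-format
    state dict; nothing is ever downloaded.

    Raises
    ------
    MobileNetUnavailableError
        If torch/torchvision are not installed or ``weights_path`` is not
        provided; the error directs callers to the texture fallback.
    """
    try:
        import torch
        from torchvision.models import mobilenet_v2
    except ImportError as exc:
        raise MobileNetUnavailableError(
            "torch/torchvision are not installed; install the 'mobilenet' "
            "extra or use extract_texture_stats"
        ) from exc
    if weights_path is None:
        raise MobileNetUnavailableError(
            "no local MobileNetV2 weights supplied (weights are never "
            "downloaded); pass weights_path or use extract_texture_stats"
        )
    model = mobilenet_v2(weights=None)
    state = torch.load(weights_path, map_location="cpu")
    model.load_state_dict(state)
    model.eval()
    arr = image.pixels.astype(np.float32) / (image.levels - 1)
    if label_map is not None:
        label_map = np.asarray(label_map)
        if label_map.shape != image.shape:
            raise FeatureError("label map shape does not match image")
    with torch.no_grad():
        x = torch.from_numpy(arr)[None, None]
        x = torch.nn.functional.interpolate(
            x, size=(224, 224), mode="bilinear", align_corners=False
        ).repeat(1, 3, 1, 1)
        feats = model.features(x)
        pooled = torch.nn.functional.adaptive_avg_pool2d(feats, 1).flatten(1)
    return FeatureVector(pooled[0].numpy().astype(float), extractor_id="mobilenet_v2")
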