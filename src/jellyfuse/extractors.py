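"""Pluggable image-to-feature adapter.

Turns a directory of PNG/JPEG images into a :class:`FeatureBlock` through a
user-supplied *backbone*: any callable mapping an ``H x W x C`` float array
to a 1-D feature vector.  The adapter pools or tiles the backbone's output
to the requested width, since different backbones emit different native
widths.  No deep-learning framework is imported here — a pre-trained CNN
wrapped in a closure works, and so does the deterministic mock backbone used
in tests.  Without a backbone the adapter refuses to run and points users to
the synthetic-data path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fusion import FeatureBlock

__all__ = [
    "ExtractorSpec",
    "ExtractionUnavailableError",
    "extract_features",
    "pixel_mean_backbone",
    "pool_to_dim",
]

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


class ExtractionUnavailableError(RuntimeError):
    """No backbone is available; feature extraction cannot run."""


@dataclass(frozen=True)
class ExtractorSpec:
    """Identity and output width of one extractor."""

    backbone_id: str
    target_dim: int
    pooling: str = "mean"

    def __post_init__(self):
        if self.target_dim < 1:
            raise ValueError("target_dim must be at least 1")
        if self.pooling != "mean":
            raise ValueError("only 'mean' pooling is implemented")


def pool_to_dim(vector: np.ndarray, target_dim: int) -> np.ndarray:
    """Reduce (group-average) or tile a feature vector to ``target_dim``."""
    v = np.asarray(vector, dtype=float).ravel()
    if v.size == target_dim:
        return v
    if v.size > target_dim:
        # contiguous groups, averaged; group sizes differ by at most one
        edges = np.linspace(0, v.size, target_dim + 1).astype(int)
        return np.array([v[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    return np.resize(v, target_dim)


def pixel_mean_backbone(image: np.ndarray) -> np.ndarray:
    """Deterministic mock backbone: per-channel pixel means."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    return img.mean(axis=(0, 1))


def extract_features(image_dir, spec: ExtractorSpec, backbone=None) -> FeatureBlock:
    """Run *backbone* over every image in *image_dir* (sorted by name) and
    pool each output to ``spec.target_dim`` columns."""
    if backbone is None:
        raise ExtractionUnavailableError(
            "no backbone supplied (pre-trained weights are not bundled); "
            "pass a callable backbone, or use jellyfuse.synthetic to generate "
            "feature tables without images"
        )
    paths = sorted(
        p for p in Path(image_dir).iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not paths:
        raise FileNotFoundError(f"no PNG/JPEG images under {image_dir}")
    from PIL import Image

    rows = []
    for p in paths:
        with Image.open(p) as im:
            arr = np.asarray(im, dtype=float)
        rows.append(pool_to_dim(backbone(arr), spec.target_dim))
    return FeatureBlock(spec.backbone_id, np.vstack(rows))
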