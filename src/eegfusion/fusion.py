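"""Pixel-level weighted-average fusion of regional multispectral images.

Fusion forms, per pixel and per color channel, the convex combination
``Y = sum_n A_n * X_n`` with non-negative weights summing to one. Because
the weights are constant across pixels, per-pixel and whole-image weighted
averaging coincide; the operation is implemented once, channelwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .montage import REGIONS
from .topomap import MultispectralImage

__all__ = ["FusionWeights", "FusionError", "fuse_images"]


class FusionError(ValueError):
    """Raised for invalid fusion weights or incompatible images."""


@dataclass(frozen=True)
class FusionWeights:
    """Non-negative per-region weights summing to one."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", dict(self.weights))
        vals = np.array(list(self.weights.values()), dtype=float)
        if np.any(vals < 0):
            raise FusionError("fusion weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise FusionError(f"fusion weights must sum to 1, got {vals.sum():.12g}")

    @classmethod
    def uniform(cls, regions: Sequence[str] = REGIONS) -> "FusionWeights":
        return cls({r: 1.0 / len(regions) for r in regions})

    def for_regions(self, regions: Sequence[str]) -> np.ndarray:
        missing = [r for r in regions if r not in self.weights]
        if missing:
            raise FusionError(f"no weight for regions {missing}")
        return np.array([self.weights[r] for r in regions], dtype=float)


def fuse_images(
    images: Sequence[MultispectralImage],
    w: FusionWeights | Mapping[str, float] | None = None,
) -> MultispectralImage:
    """Weighted-average fusion of regional images into one image tagged "fused".

    All images must share shape and grid window, carry distinct region tags,
    and have exactly one weight each. ``w`` defaults to uniform weights over
    the images' regions.
    """
    if not images:
        raise FusionError("no images to fuse")
    regions = [img.region for img in images]
    if len(set(regions)) != len(regions):
        raise FusionError(f"duplicate region tags in fusion input: {regions}")
    shape0, bounds0 = images[0].pixels.shape, images[0].grid_bounds
    for img in images[1:]:
        if img.pixels.shape != shape0:
            raise FusionError("images to fuse must share the same shape")
        if not np.allclose(img.grid_bounds, bounds0, atol=1e-12):
            raise FusionError("images to fuse must share the same grid window")

    if w is None:
        w = FusionWeights.uniform(regions)
    elif not isinstance(w, FusionWeights):
        w = FusionWeights(dict(w))
    extra = set(w.weights) - set(regions)
    if extra:
        raise FusionError(f"weights given for regions not being fused: {sorted(extra)}")
    a = w.for_regions(regions)

    stack = np.stack([img.pixels for img in images])  # n x H x W x 3
    fused = np.tensordot(a, stack, axes=(0, 0))
    return MultispectralImage(np.clip(fused, 0.0, 1.0), "fused", bounds0)
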