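"""Corpus harmonization: bring heterogeneous corpora to one shape/depth.

The two annotated corpora differ in resolution (256x256 RGB-derived vs
696x520 gray) and the application corpus is 512x512, so everything is
mapped to a common target (default 256x256, single channel, intensities
in [0, 1]) before any model sees it. Density maps are re-normalized
after resizing so total mass — and hence the implied count — is exact;
masks are resized with nearest-neighbour interpolation so they stay
binary.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import transform

from .simdata import SyntheticDataset, SyntheticSample

__all__ = ["PreprocessSpec", "to_grayscale", "resize_image",
           "normalize_intensity", "harmonize"]

#: Rec. 601 luma weights
DEFAULT_GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclasses.dataclass(frozen=True)
class PreprocessSpec:
    target_height: int = 256
    target_width: int = 256
    grayscale_weights: tuple[float, float, float] = DEFAULT_GRAY_WEIGHTS
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self):
        if self.target_height < 16 or self.target_width < 16:
            raise ValueError("target dimensions must be >= 16")
        w = np.asarray(self.grayscale_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("grayscale weights must be non-negative and sum to 1")
        lo, hi = self.intensity_range
        if not hi > lo:
            raise ValueError("intensity_range must satisfy high > low")


def to_grayscale(image: np.ndarray,
                 weights=DEFAULT_GRAY_WEIGHTS) -> np.ndarray:
    """Collapse an H x W x 3 RGB image to one channel by a weighted sum."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected 3 channels (H x W x 3 input)")
    w = np.asarray(weights, dtype=float)
    return image @ w


def resize_image(image: np.ndarray, target_height: int, target_width: int,
                 interpolation: str = "bilinear") -> np.ndarray:
    """Resize to exactly (target_height, target_width).

    ``bilinear`` for images and density maps, ``nearest`` for masks
    (preserves binarity). Aspect ratio is *not* preserved: non-square
    frames are stretched onto the square target.
    """
    if target_height <= 0 or target_width <= 0:
        raise ValueError("target dimensions must be positive")
    order = {"nearest": 0, "bilinear": 1}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    image = np.asarray(image, dtype=float)
    out = transform.resize(image, (target_height, target_width), order=order,
                           mode="edge", anti_aliasing=(order == 1),
                           preserve_range=True)
    return out


def resize_density_map(dmap: np.ndarray, target_height: int,
                       target_width: int) -> np.ndarray:
    """Bilinear resize followed by multiplicative mass re-normalization,
    so ``count = mass / density_scale`` survives the shape change."""
    before = float(np.sum(dmap))
    out = resize_image(dmap, target_height, target_width, "bilinear")
    out = np.clip(out, 0.0, None)
    after = float(np.sum(out))
    if before > 0 and after > 0:
        out *= before / after
    elif before == 0:
        out[:] = 0.0
    return out


def normalize_intensity(image: np.ndarray, intensity_range=(0.0, 255.0)) -> np.ndarray:
    """Affinely map [low, high] to [0, 1], clipping outliers."""
    lo, hi = float(intensity_range[0]), float(intensity_range[1])
    if not hi > lo:
        raise ValueError("degenerate intensity range")
    return np.clip((np.asarray(image, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def harmonize(dataset: SyntheticDataset, spec: PreprocessSpec) -> SyntheticDataset:
    """Resize every sample's three channels to the spec target and rescale
    image intensities to [0, 1]. Count labels are never touched."""
    th, tw = spec.target_height, spec.target_width
    out_samples = []
    for s in dataset.samples:
        img = s.image
        if img.ndim == 3:
            img = to_grayscale(img, spec.grayscale_weights)
        if img.shape != (th, tw):
            img = resize_image(img, th, tw, "bilinear")
        img = normalize_intensity(img, spec.intensity_range)
        dmap = (s.density_map if s.density_map.shape == (th, tw)
                else resize_density_map(s.density_map, th, tw))
        mask = s.foreground_mask
        if mask.shape != (th, tw):
            mask = resize_image(mask, th, tw, "nearest").astype(np.uint8)
        out_samples.append(SyntheticSample(image=img, density_map=dmap,
                                           foreground_mask=mask,
                                           centers=s.centers, count=s.count))
    cfg = dataclasses.replace(dataset.config, height=th, width=tw)
    return SyntheticDataset(out_samples, cfg, name=dataset.name)
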