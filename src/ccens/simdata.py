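"""Synthetic fluorescence-microscopy scene generator.

Produces images with the two kinds of ground-truth annotation used for
counting by regression: a *dot density map*, in which every cell
contributes an isotropic Gaussian kernel of fixed mass ``density_scale``
(so that ``sum(map) / density_scale`` recovers the count), and a binary
*foreground mask* marking cell pixels. Three presets emulate the corpora
the models are trained and applied on:

``dot``
    256x256 scenes, counts ~ Normal(174, 64) truncated below at 1 — a
    high-density corpus annotated with dot density maps.
``mask``
    696x520 scenes, counts uniform on [1, 100], annotated with
    foreground masks (resized downstream to 256x256).
``real``
    512x512 scenes emulating nuclei-stained organoid images whose counts
    are unknown to the models; used for group comparisons.

Coordinates are row-major, 0-based; cell centers may be fractional, and
masks / density maps are sampled at pixel centers.
"""

from __future__ import annotations

import csv
import dataclasses
import pathlib
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "DistSpec", "SceneConfig", "CellInstance", "SyntheticSample",
    "SyntheticDataset", "LayoutInfeasibleError", "sample_layout",
    "render_density_map", "render_foreground_mask", "render_image",
    "generate_sample", "generate_dataset", "preset_config",
    "save_dataset", "load_dataset",
]

#: intensity ceiling for rendered images (8-bit convention)
INTENSITY_MAX = 255.0

#: rejection-sampling budget per cell for non-overlapping layouts
RETRY_FACTOR = 100

#: extra center separation (px) beyond the sum of radii in non-overlapping
#: layouts, so rasterized disks can never touch even diagonally and the
#: mask's connected-component count equals the cell count
NONOVERLAP_MARGIN = 1.5


class LayoutInfeasibleError(RuntimeError):
    """Raised when a non-overlapping layout cannot be placed."""


@dataclasses.dataclass(frozen=True)
class DistSpec:
    """A small distribution spec: constant, uniform, uniform_int,
    normal, or truncated normal (``low``/``high`` clip bounds)."""

    kind: str
    value: float = 0.0
    low: float = 0.0
    high: float = 1.0
    mean: float = 0.0
    sd: float = 1.0

    def draw(self, rng: np.random.Generator, size=None):
        if self.kind == "constant":
            out = np.full(size if size is not None else (), self.value, dtype=float)
        elif self.kind == "uniform":
            out = rng.uniform(self.low, self.high, size=size)
        elif self.kind == "uniform_int":
            out = rng.integers(int(self.low), int(self.high) + 1,
                               size=size).astype(float)
        elif self.kind in ("normal", "normal_trunc"):
            out = rng.normal(self.mean, self.sd, size=size)
            if self.kind == "normal_trunc":
                # redraw out-of-range values rather than clip, so the
                # configured mean/sd are only mildly distorted
                out = np.atleast_1d(out)
                bad = (out < self.low) | (out > self.high)
                tries = 0
                while bad.any() and tries < 1000:
                    out[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
                    bad = (out < self.low) | (out > self.high)
                    tries += 1
                out = np.clip(out, self.low, self.high)
                if size is None:
                    out = out[0]
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        return out

    def draw_count(self, rng: np.random.Generator) -> int:
        n = int(round(float(self.draw(rng))))
        return max(n, 0)


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Full description of one scene-generation regime."""

    height: int = 256
    width: int = 256
    count_law: DistSpec = DistSpec("normal_trunc", mean=174, sd=64, low=1, high=400)
    cell_radius_law: DistSpec = DistSpec("uniform", low=2.0, high=4.0)
    overlap_allowed: bool = True
    cluster_strength: float = 0.0
    intensity_law: DistSpec = DistSpec("uniform", low=120.0, high=220.0)
    noise_sd: float = 4.0
    blur_sigma: float = 0.8
    background_level: float = 8.0
    density_sigma: float = 2.0
    density_scale: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ValueError("scene dimensions must be >= 16 pixels")
        if self.density_sigma <= 0 or self.density_scale <= 0:
            raise ValueError("density_sigma and density_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cluster_strength < 0:
            raise ValueError("cluster_strength must be non-negative")


@dataclasses.dataclass(frozen=True)
class CellInstance:
    center_row: float
    center_col: float
    radius: float
    peak_intensity: float


@dataclasses.dataclass
class SyntheticSample:
    image: np.ndarray
    density_map: np.ndarray
    foreground_mask: np.ndarray
    centers: list[CellInstance]
    count: int

    def validate(self, density_scale: float | None = None):
        if self.count != len(self.centers):
            raise ValueError("count must equal the number of cell instances")
        if not np.isin(self.foreground_mask, (0, 1)).all():
            raise ValueError("foreground mask must be strictly binary")
        if (self.density_map < 0).any():
            raise ValueError("density map must be non-negative")
        shapes = {self.image.shape, self.density_map.shape,
                  self.foreground_mask.shape}
        if len(shapes) != 1:
            raise ValueError("image, density map and mask must share one shape")


@dataclasses.dataclass
class SyntheticDataset:
    samples: list[SyntheticSample]
    config: SceneConfig
    name: str = ""

    def __len__(self):
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def counts(self) -> np.ndarray:
        return np.array([s.count for s in self.samples], dtype=float)

    def images(self) -> np.ndarray:
        return np.stack([s.image for s in self.samples])

    def density_maps(self) -> np.ndarray:
        return np.stack([s.density_map for s in self.samples])

    def masks(self) -> np.ndarray:
        return np.stack([s.foreground_mask for s in self.samples])


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def sample_layout(config: SceneConfig, n_cells: int,
                  rng: np.random.Generator) -> list[CellInstance]:
    """Place ``n_cells`` cells inside the frame.

    Uniform placement by default; with ``cluster_strength > 0`` centers
    are drawn around a handful of cluster seeds with spread shrinking as
    the strength grows. With ``overlap_allowed=False`` candidate centers
    are rejection-sampled until all pairwise center distances exceed the
    sum of radii, within a budget of ``RETRY_FACTOR * n_cells`` draws.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if n_cells == 0:
        return []
    h, w = config.height, config.width

    def draw_center():
        if config.cluster_strength > 0:
            c = cluster_seeds[rng.integers(len(cluster_seeds))]
            spread = min(h, w) / (2.0 * (1.0 + config.cluster_strength))
            r = np.clip(c[0] + rng.normal(0, spread), 0, h - 1e-6)
            col = np.clip(c[1] + rng.normal(0, spread), 0, w - 1e-6)
            return r, col
        return rng.uniform(0, h), rng.uniform(0, w)

    if config.cluster_strength > 0:
        n_seeds = max(1, int(np.ceil(n_cells / 30)))
        cluster_seeds = [(rng.uniform(0, h), rng.uniform(0, w))
                         for _ in range(n_seeds)]

    cells: list[CellInstance] = []
    budget = RETRY_FACTOR * n_cells
    attempts = 0
    while len(cells) < n_cells:
        if attempts >= budget and not config.overlap_allowed:
            raise LayoutInfeasibleError(
                f"layout infeasible: placed {len(cells)}/{n_cells} cells in "
                f"{attempts} attempts on a {h}x{w} frame")
        attempts += 1
        r, c = draw_center()
        radius = float(config.cell_radius_law.draw(rng))
        radius = max(radius, 0.5)
        if not config.overlap_allowed:
            ok = all((r - cc.center_row) ** 2 + (c - cc.center_col) ** 2
                     >= (radius + cc.radius + NONOVERLAP_MARGIN) ** 2
                     for cc in cells)
            if not ok:
                continue
        peak = float(np.clip(config.intensity_law.draw(rng), 1.0, INTENSITY_MAX))
        cells.append(CellInstance(float(r), float(c), radius, peak))
    return cells


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_density_map(centers: Sequence[CellInstance], shape, sigma: float,
                       scale: float) -> np.ndarray:
    """Superpose one Gaussian kernel of mass ``scale`` per cell.

    Each kernel is evaluated on a local (+-4 sigma) window at pixel
    centers and normalized to mass ``scale`` before placement, so only
    border truncation can remove mass.
    """
    if sigma <= 0 or scale <= 0:
        raise ValueError("sigma and scale must be positive")
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    dmap = np.zeros((h, w), dtype=np.float64)
    reach = int(np.ceil(4 * sigma))
    for cell in centers:
        r0 = int(np.floor(cell.center_row)) - reach
        c0 = int(np.floor(cell.center_col)) - reach
        rows = np.arange(r0, r0 + 2 * reach + 1)
        cols = np.arange(c0, c0 + 2 * reach + 1)
        g = (np.exp(-((rows - cell.center_row) ** 2) / (2 * sigma ** 2))[:, None]
             * np.exp(-((cols - cell.center_col) ** 2) / (2 * sigma ** 2))[None, :])
        g *= scale / g.sum()
        rs = slice(max(r0, 0), min(r0 + 2 * reach + 1, h))
        cs = slice(max(c0, 0), min(c0 + 2 * reach + 1, w))
        dmap[rs, cs] += g[rs.start - r0: rs.stop - r0, cs.start - c0: cs.stop - c0]
    return dmap


def render_foreground_mask(centers: Sequence[CellInstance], shape) -> np.ndarray:
    """Binary union of per-cell disks sampled at pixel centers."""
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    mask = np.zeros((h, w), dtype=np.uint8)
    for cell in centers:
        rad = cell.radius
        r0 = max(int(np.floor(cell.center_row - rad)), 0)
        r1 = min(int(np.ceil(cell.center_row + rad)) + 1, h)
        c0 = max(int(np.floor(cell.center_col - rad)), 0)
        c1 = min(int(np.ceil(cell.center_col + rad)) + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1)[:, None] - cell.center_row
        cc = np.arange(c0, c1)[None, :] - cell.center_col
        mask[r0:r1, c0:c1] |= (rr * rr + cc * cc <= rad * rad).astype(np.uint8)
    return mask


def render_image(centers: Sequence[CellInstance], config: SceneConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Forward imaging model: background + per-cell radial Gaussian
    profiles (width radius/2), optical blur, additive Gaussian noise,
    clipped to [0, INTENSITY_MAX]. Deterministic under a fixed rng state.
    """
    h, w = config.height, config.width
    img = np.full((h, w), float(config.background_level), dtype=np.float64)
    for cell in centers:
        prof_sigma = max(cell.radius / 2.0, 0.5)
        reach = int(np.ceil(3 * prof_sigma)) + 1
        r0 = int(np.floor(cell.center_row)) - reach
        c0 = int(np.floor(cell.center_col)) - reach
        rows = np.arange(r0, r0 + 2 * reach + 1)
        cols = np.arange(c0, c0 + 2 * reach + 1)
        g = (np.exp(-((rows - cell.center_row) ** 2) / (2 * prof_sigma ** 2))[:, None]
             * np.exp(-((cols - cell.center_col) ** 2) / (2 * prof_sigma ** 2))[None, :])
        rs = slice(max(r0, 0), min(r0 + 2 * reach + 1, h))
        cs = slice(max(c0, 0), min(c0 + 2 * reach + 1, w))
        img[rs, cs] += cell.peak_intensity * g[rs.start - r0: rs.stop - r0,
                                               cs.start - c0: cs.stop - c0]
    if config.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, config.blur_sigma)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, INTENSITY_MAX)


def generate_sample(config: SceneConfig, rng: np.random.Generator) -> SyntheticSample:
    """Draw a count from the configured law, lay out the cells and render
    all three channels."""
    n = config.count_law.draw_count(rng)
    centers = sample_layout(config, n, rng)
    shape = (config.height, config.width)
    sample = SyntheticSample(
        image=render_image(centers, config, rng),
        density_map=render_density_map(centers, shape, config.density_sigma,
                                       config.density_scale),
        foreground_mask=render_foreground_mask(centers, shape),
        centers=centers,
        count=n,
    )
    sample.validate()
    return sample


def generate_dataset(config: SceneConfig, n_samples: int,
                     seed: int | None = None, name: str = "") -> SyntheticDataset:
    """Generate ``n_samples`` independent scenes, reproducibly per seed."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if seed is None:
        seed = config.seed
    children = np.random.SeedSequence(seed).spawn(n_samples)
    samples = [generate_sample(config, np.random.default_rng(s)) for s in children]
    return SyntheticDataset(samples, config, name=name)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_config(preset: str, height: int | None = None,
                  width: int | None = None, seed: int = 0,
                  **overrides) -> SceneConfig:
    """The three canonical corpus regimes (see module docstring).

    ``height``/``width`` scale a preset down while keeping its count law
    and annotation structure; further keyword overrides are applied last.
    """
    if preset == "dot":
        base = dict(height=256, width=256,
                    count_law=DistSpec("normal_trunc", mean=174, sd=64,
                                       low=1, high=400),
                    cell_radius_law=DistSpec("uniform", low=2.0, high=4.0),
                    overlap_allowed=True, cluster_strength=0.0)
    elif preset == "mask":
        base = dict(height=520, width=696,
                    count_law=DistSpec("uniform_int", low=1, high=100),
                    cell_radius_law=DistSpec("uniform", low=3.0, high=6.0),
                    overlap_allowed=True, cluster_strength=0.0)
    elif preset == "real":
        base = dict(height=512, width=512,
                    count_law=DistSpec("normal_trunc", mean=40, sd=15,
                                       low=1, high=120),
                    cell_radius_law=DistSpec("uniform", low=3.0, high=6.0),
                    overlap_allowed=True, cluster_strength=2.0)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    if height is not None:
        base["height"] = height
    if width is not None:
        base["width"] = width
    base["seed"] = seed
    base.update(overrides)
    return SceneConfig(**base)


# ---------------------------------------------------------------------------
# disk layout: images/ density/ masks/ + manifest.csv
# ---------------------------------------------------------------------------

def save_dataset(dataset: SyntheticDataset, out_dir, split: str = "train"):
    """Write a corpus directory: 8-bit PNGs for images and masks, the
    density maps both as 8-bit preview PNGs and lossless float32 TIFFs,
    and a ``manifest.csv`` with columns filename,count,split."""
    out = pathlib.Path(out_dir)
    for sub in ("images", "density", "masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(dataset.samples):
        fname = f"sample_{i:05d}.png"
        iio.imwrite(out / "images" / fname,
                    np.clip(s.image, 0, 255).astype(np.uint8))
        iio.imwrite(out / "masks" / fname,
                    (s.foreground_mask * 255).astype(np.uint8))
        peak = s.density_map.max()
        preview = (s.density_map / peak * 255) if peak > 0 else s.density_map
        iio.imwrite(out / "density" / fname, preview.astype(np.uint8))
        tifffile.imwrite(out / "density" / (fname[:-4] + ".tif"),
                         s.density_map.astype(np.float32))
        rows.append((fname, s.count, split))
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "count", "split"])
        writer.writerows(rows)
    return out


def load_dataset(in_dir, config: SceneConfig | None = None) -> SyntheticDataset:
    """Read a corpus directory written by :func:`save_dataset`."""
    root = pathlib.Path(in_dir)
    samples = []
    with open(root / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            fname = row["filename"]
            image = iio.imread(root / "images" / fname).astype(np.float64)
            mask_png = root / "masks" / fname
            mask = ((iio.imread(mask_png) > 127).astype(np.uint8)
                    if mask_png.exists() else np.zeros_like(image, dtype=np.uint8))
            dens_tif = root / "density" / (fname[:-4] + ".tif")
            dens = (tifffile.imread(dens_tif).astype(np.float64)
                    if dens_tif.exists() else np.zeros_like(image))
            samples.append(SyntheticSample(image=image, density_map=dens,
                                           foreground_mask=mask, centers=[],
                                           count=int(row["count"])))
    shape = samples[0].image.shape if samples else (256, 256)
    cfg = config or SceneConfig(height=shape[0], width=shape[1])
    return SyntheticDataset(samples, cfg, name=root.name)
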