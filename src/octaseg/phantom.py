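"""Synthetic OCTA vessel phantoms.

En-face OCTA projections show two vascular layers with different contrast:
a bright, thick superficial complex (SVC) annotated at pixel level, and a
dim, thin deep complex (DVC) annotated only along 1-px centerlines.  The
generator emulates both layers as random branching walks, renders them with
the contrast ordering real acquisitions show (SVC > DVC > background), and
corrupts the image — never the masks — with multiplicative speckle and
row-wise sinusoidal stripe artifacts mimicking motion/projection noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.morphology import dilation, disk


class ConfigurationError(ValueError):
    """Raised when a phantom configuration field is invalid."""


@dataclass(frozen=True)
class PhantomConfig:
    size: int = 64
    n_superficial_trees: int = 3
    n_deep_trees: int = 5
    superficial_width_range: tuple[int, int] = (2, 6)
    deep_width_range: tuple[int, int] = (1, 2)
    speckle_sigma: float = 0.1
    stripe_amplitude: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.size < 32:
            raise ConfigurationError(f"size must be >= 32, got {self.size}")
        for name in ("superficial_width_range", "deep_width_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} must be positive and ordered, "
                                         f"got {(lo, hi)}")
        if self.deep_width_range[1] > self.superficial_width_range[1]:
            raise ConfigurationError(
                "deep_width_range widths must not exceed superficial_width_range")
        if self.n_superficial_trees < 0:
            raise ConfigurationError("n_superficial_trees must be >= 0")
        if self.n_deep_trees < 0:
            raise ConfigurationError("n_deep_trees must be >= 0")
        if self.speckle_sigma < 0:
            raise ConfigurationError("speckle_sigma must be >= 0")
        if self.stripe_amplitude < 0:
            raise ConfigurationError("stripe_amplitude must be >= 0")


@dataclass
class ImageSample:
    """One phantom: image in [0,1], pixel-level SVC mask, centerline DVC mask."""

    image: np.ndarray
    svc_mask: np.ndarray
    dvc_mask: np.ndarray
    sample_id: int
    split: str = "train"

    def validate(self) -> None:
        assert self.image.shape == self.svc_mask.shape == self.dvc_mask.shape
        assert self.image.min() >= 0 and self.image.max() <= 1
        for m in (self.svc_mask, self.dvc_mask):
            assert set(np.unique(m)).issubset({0, 1})


# -- vessel-tree growth ----------------------------------------------------


def _border_start(rng: np.random.Generator, size: int):
    side = rng.integers(4)
    t = rng.uniform(0.1, 0.9) * size
    if side == 0:
        return np.array([0.0, t]), rng.uniform(0.25, 0.75) * math.pi  # top
    if side == 1:
        return np.array([size - 1.0, t]), -rng.uniform(0.25, 0.75) * math.pi
    if side == 2:
        return np.array([t, 0.0]), rng.uniform(-0.25, 0.25) * math.pi
    return np.array([t, size - 1.0]), math.pi - rng.uniform(-0.25, 0.25) * math.pi


def _grow_tree(rng: np.random.Generator, size: int) -> list[np.ndarray]:
    """Random recursive branching walk; returns a list of float paths.

    The heading angle convention is (d_row, d_col) = (sin a, cos a); turns
    are small per-step jitters, branch events fork at 20-60 degrees.
    """
    start, heading = _border_start(rng, size)
    n_branches = int(rng.integers(1, 4))
    max_len = size * 1.5
    paths = []
    stack = [(start, heading, max_len, 0)]
    while stack:
        pos, a, budget, depth = stack.pop()
        path = [pos.copy()]
        steps = int(budget)
        branch_steps = set(rng.integers(5, max(6, steps), size=n_branches)) \
            if depth == 0 and steps > 6 else set()
        for s in range(steps):
            a += rng.normal(0.0, 0.12)
            pos = pos + np.array([math.sin(a), math.cos(a)])
            if not (0 <= pos[0] < size and 0 <= pos[1] < size):
                break
            path.append(pos.copy())
            if s in branch_steps and depth < 2:
                sign = 1 if rng.random() < 0.5 else -1
                fork = a + sign * math.radians(rng.uniform(20, 60))
                stack.append((pos.copy(), fork, budget * 0.5, depth + 1))
        if len(path) > 2:
            paths.append(np.array(path))
    return paths


def _rasterize_path(path: np.ndarray, size: int) -> list[tuple[int, int]]:
    """Round a float path to an 8-connected pixel chain with staircase corners pruned."""
    pts = np.clip(np.rint(path).astype(int), 0, size - 1)
    chain: list[tuple[int, int]] = []
    for p in map(tuple, pts):
        if not chain or p != chain[-1]:
            chain.append(p)
    # drop corner pixels whose neighbours are already 8-adjacent
    pruned = []
    i = 0
    while i < len(chain):
        if 0 < i < len(chain) - 1:
            (r0, c0), (r2, c2) = chain[i - 1], chain[i + 1]
            if max(abs(r0 - r2), abs(c0 - c2)) <= 1:
                i += 1
                continue
        pruned.append(chain[i])
        i += 1
    return pruned


def _paths_to_mask(paths, size: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=np.uint8)
    for path in paths:
        for r, c in _rasterize_path(path, size):
            mask[r, c] = 1
    return mask


# -- rendering -------------------------------------------------------------


def _widen(centerline: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return centerline.copy()
    if width == 2:
        return dilation(centerline, np.ones((2, 2), dtype=np.uint8))
    return dilation(centerline, disk(width // 2))


def generate_phantom(config: PhantomConfig, sample_id: int) -> ImageSample:
    """Render one phantom; deterministic given (config.seed, sample_id)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, sample_id)))
    size = config.size

    base = 0.12 + 0.05 * gaussian_filter(rng.standard_normal((size, size)), 4.0)
    image = np.clip(base, 0.0, 0.3)

    # deep layer first: dim thin vessels, centerline ground truth
    dvc_mask = np.zeros((size, size), dtype=np.uint8)
    for _ in range(config.n_deep_trees):
        paths = _grow_tree(rng, size)
        center = _paths_to_mask(paths, size)
        lo, hi = config.deep_width_range
        rendered = _widen(center, int(rng.integers(lo, hi + 1)))
        image[rendered > 0] = rng.uniform(0.3, 0.6)
        dvc_mask |= center

    # superficial layer on top: bright thick vessels, pixel-level ground truth
    svc_mask = np.zeros((size, size), dtype=np.uint8)
    for _ in range(config.n_superficial_trees):
        paths = _grow_tree(rng, size)
        center = _paths_to_mask(paths, size)
        lo, hi = config.superficial_width_range
        rendered = _widen(center, int(rng.integers(lo, hi + 1)))
        image[rendered > 0] = rng.uniform(0.7, 1.0)
        svc_mask |= rendered.astype(np.uint8)

    # imaging artifacts touch the image only, never the masks
    image = image * (1.0 + config.speckle_sigma * rng.standard_normal((size, size)))
    period = rng.uniform(8.0, 24.0)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    gain = 1.0 + config.stripe_amplitude * np.sin(
        2.0 * math.pi * np.arange(size) / period + phase)
    image = image * gain[:, None]

    return ImageSample(image=np.clip(image, 0.0, 1.0),
                       svc_mask=svc_mask, dvc_mask=dvc_mask,
                       sample_id=sample_id)


def generate_dataset(config: PhantomConfig, n: int,
                     train_fraction: float = 0.7) -> list[ImageSample]:
    """n phantoms with a deterministic train/val split (default 7:3)."""
    if n < 2:
        raise ValueError("need n >= 2 to populate both splits")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5111)))
    n_train = int(math.floor(n * train_fraction))
    perm = rng.permutation(n)
    train_ids = set(perm[:n_train].tolist())
    samples = []
    for i in range(n):
        s = generate_phantom(config, i)
        s.split = "train" if i in train_ids else "val"
        samples.append(s)
    return samples


def insert_gaps(mask: np.ndarray, rng: np.random.Generator,
                n_gaps: int = 4, max_gap: int = 3) -> np.ndarray:
    """Cut short (1 to max_gap px) holes into a binary vessel mask.

    Emulates the breakpoint failure mode of an imperfect segmentation:
    each gap zeroes an LxL square centred on a random foreground pixel.
    """
    out = mask.copy()
    fg = np.argwhere(mask > 0)
    if len(fg) == 0:
        return out
    for _ in range(n_gaps):
        r, c = fg[rng.integers(len(fg))]
        L = int(rng.integers(1, max_gap + 1))
        r0, c0 = max(0, r - L // 2), max(0, c - L // 2)
        out[r0:r0 + L, c0:c0 + L] = 0
    return out


# -- disk layout -----------------------------------------------------------


def write_dataset(samples: list[ImageSample], root: str | Path) -> None:
    """Emit <root>/{train,val}/{img,gt_svc,gt_dvc}/<id>.png (8-bit, masks {0,255})."""
    root = Path(root)
    for s in samples:
        base = root / s.split
        for sub in ("img", "gt_svc", "gt_dvc"):
            (base / sub).mkdir(parents=True, exist_ok=True)
        name = f"{s.sample_id:04d}.png"
        Image.fromarray((s.image * 255).round().astype(np.uint8)).save(
            base / "img" / name)
        Image.fromarray((s.svc_mask * 255).astype(np.uint8)).save(
            base / "gt_svc" / name)
        Image.fromarray((s.dvc_mask * 255).astype(np.uint8)).save(
            base / "gt_dvc" / name)
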