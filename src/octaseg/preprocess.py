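"""Fixed-region CLAHE and joint geometric augmentation.

OCTA en-face projections concentrate the hard-to-see deep-capillary detail
in a central window; contrast-limited adaptive histogram equalisation is
therefore applied to a fixed region of interest only, leaving the rest of
the image untouched.  Augmentation applies one geometric transform jointly
to the image and both masks, restricted to right-angle rotations and flips
so masks stay exactly binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.exposure import equalize_adapthist

from .phantom import ImageSample


@dataclass(frozen=True)
class PreprocessSettings:
    """Fixed-region CLAHE and augmentation geometry used by the trainer.

    roi gives explicit (row_start, row_end, col_start, col_end) bounds;
    when None the central roi_fraction window is used.  crop_size None
    means no cropping (rotations and flips only).
    """

    roi: tuple[int, int, int, int] | None = None
    roi_fraction: float = 0.5
    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)
    crop_size: int | None = None

    def resolve_roi(self, h: int, w: int) -> "RegionOfInterest":
        if self.roi is not None:
            return RegionOfInterest(*self.roi)
        return central_roi(h, w, self.roi_fraction)


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open [start, end) pixel bounds of the equalised window."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def validate(self, h: int, w: int) -> None:
        if not (0 <= self.row_start < self.row_end <= h):
            raise ValueError(f"row bounds {self.row_start}:{self.row_end} "
                             f"invalid for height {h}")
        if not (0 <= self.col_start < self.col_end <= w):
            raise ValueError(f"col bounds {self.col_start}:{self.col_end} "
                             f"invalid for width {w}")


def central_roi(h: int, w: int, fraction: float = 0.5) -> RegionOfInterest:
    """Central fraction x fraction window (default 50%), where DVC detail sits."""
    dh, dw = int(h * fraction), int(w * fraction)
    r0, c0 = (h - dh) // 2, (w - dw) // 2
    return RegionOfInterest(r0, r0 + dh, c0, c0 + dw)


def clahe_fixed_region(image: np.ndarray, roi: RegionOfInterest,
                       clip_limit: float = 2.0,
                       tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """CLAHE computed on the ROI crop alone; pixels outside are untouched.

    clip_limit follows the 8-bit convention (typical values 1-4) and is
    mapped onto the normalised [0, 1] clip fraction of the underlying
    histogram equalisation when it exceeds 1.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    h, w = image.shape
    roi.validate(h, w)
    crop = image[roi.row_start:roi.row_end, roi.col_start:roi.col_end]
    out = image.copy()
    if crop.max() - crop.min() < 1e-12:
        return out  # constant region: equalisation is a no-op
    frac = clip_limit / 256.0 if clip_limit > 1.0 else clip_limit
    kernel = (max(1, crop.shape[0] // tile_grid[0]),
              max(1, crop.shape[1] // tile_grid[1]))
    eq = equalize_adapthist(np.clip(crop, 0.0, 1.0), kernel_size=kernel,
                            clip_limit=frac)
    out[roi.row_start:roi.row_end, roi.col_start:roi.col_end] = eq
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class AugmentParams:
    """One geometric transform: crop origin, rotation k*90deg, horizontal flip."""

    row0: int
    col0: int
    rot_k: int
    flip: bool


def draw_augment_params(rng: np.random.Generator, h: int,
                        crop_size: int) -> AugmentParams:
    return AugmentParams(row0=int(rng.integers(0, h - crop_size + 1)),
                         col0=int(rng.integers(0, h - crop_size + 1)),
                         rot_k=int(rng.integers(0, 4)),
                         flip=bool(rng.integers(0, 2)))


def _apply(arr: np.ndarray, p: AugmentParams, crop_size: int) -> np.ndarray:
    out = arr[p.row0:p.row0 + crop_size, p.col0:p.col0 + crop_size]
    out = np.rot90(out, p.rot_k)
    if p.flip:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def augment(sample: ImageSample, rng_seed: int, crop_size: int | None = None,
            params: AugmentParams | None = None) -> ImageSample:
    """Apply one transform jointly to image, svc_mask and dvc_mask.

    The transform is drawn from rng_seed unless explicit params are given;
    masks keep their exact {0,1} values (no interpolation is involved).
    """
    h = sample.image.shape[0]
    crop_size = h if crop_size is None else crop_size
    if crop_size > h:
        raise ValueError(f"crop_size {crop_size} exceeds image size {h}")
    if params is None:
        rng = np.random.default_rng(rng_seed)
        params = draw_augment_params(rng, h, crop_size)
    return ImageSample(
        image=_apply(sample.image, params, crop_size),
        svc_mask=_apply(sample.svc_mask, params, crop_size),
        dvc_mask=_apply(sample.dvc_mask, params, crop_size),
        sample_id=sample.sample_id, split=sample.split)
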