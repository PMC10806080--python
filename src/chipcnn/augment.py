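"""Label-preserving augmentation for training batches.

Three transforms, applied independently per image: vertical flip with
probability 1/2, zoom-in by a uniformly drawn extra magnification (crop back
to the original frame), and a vertical translation by a uniformly drawn
fraction of the image height with vacated rows zero-filled.  Validation and
test images are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AugmentConfig", "random_augment", "augment_batch"]


@dataclass(frozen=True)
class AugmentConfig:
    vertical_flip: bool = True
    zoom_low: float = 0.1          # extra magnification fraction
    zoom_high: float = 0.2
    shift_low: float = -0.05       # vertical translation, fraction of height
    shift_high: float = 0.05

    def __post_init__(self) -> None:
        if self.zoom_low > self.zoom_high:
            raise ValueError("zoom_low must not exceed zoom_high")
        if self.shift_low > self.shift_high:
            raise ValueError("shift_low must not exceed shift_high")
        if self.zoom_low < 0:
            raise ValueError("zoom bounds are extra magnification; must be >= 0")


def _axis_coords(n: int, factor: float) -> np.ndarray:
    """Source coordinates of an n-sample center crop of the image magnified
    by ``factor`` (pixel-center convention, matching a bilinear resize
    followed by a centered crop)."""
    zn = int(round(n * factor))
    offset = (zn - n) // 2
    return np.clip((np.arange(n) + offset + 0.5) * (n / zn) - 0.5, 0, n - 1)


def _zoom_in(img: np.ndarray, factor: float) -> np.ndarray:
    """Magnify by ``factor`` >= 1 and center-crop back to the input frame
    (bilinear interpolation)."""
    if factor == 1.0:
        return img
    h, w = img.shape[:2]
    r = _axis_coords(h, factor)
    c = _axis_coords(w, factor)
    r0 = np.floor(r).astype(np.intp)
    c0 = np.floor(c).astype(np.intp)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (r - r0)[:, None]
    fc = (c - c0)[None, :]
    if img.ndim == 3:
        fr = fr[..., None]
        fc = fc[..., None]
    top = img[r0][:, c0] * (1 - fc) + img[r0][:, c1] * fc
    bot = img[r1][:, c0] * (1 - fc) + img[r1][:, c1] * fc
    return top * (1 - fr) + bot * fr


def _shift_rows(img: np.ndarray, shift_px: int) -> np.ndarray:
    """Translate rows by ``shift_px`` (positive = downwards), zero-filling."""
    if shift_px == 0:
        return img
    out = np.zeros_like(img)
    if shift_px > 0:
        out[shift_px:] = img[:-shift_px]
    else:
        out[:shift_px] = img[-shift_px:]
    return out


def random_augment(pixels: np.ndarray, config: AugmentConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Apply one random draw of the augmentation pipeline to one image.

    The output has the input's shape and dtype-range ([0, 1]); sub-pixel
    shifts are rounded to whole rows.
    """
    img = np.asarray(pixels, dtype=np.float32)
    if config.vertical_flip and rng.random() < 0.5:
        img = img[::-1].copy()
    factor = 1.0 + rng.uniform(config.zoom_low, config.zoom_high)
    img = _zoom_in(img, factor)
    h = img.shape[0]
    shift = int(round(rng.uniform(config.shift_low, config.shift_high) * h))
    img = _shift_rows(img, shift)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def augment_batch(batch: np.ndarray, config: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Augment every image of a ``(N, H, W, C)`` batch independently."""
    return np.stack([random_augment(img, config, rng) for img in batch])
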