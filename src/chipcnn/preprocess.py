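"""From chip image sets to fixed-size network inputs and the study partition.

The pipeline mirrors a typical small-imaging-study design: crop the 16
inter-pillar ROIs from a stitched chip image, keep 7 informative z-slices out
of 27 (dropping near-duplicate neighbours), resize each grayscale slice to
64x64, replicate it to 3 channels, and split the images into train /
validation / test where the test set consists of one whole held-out chip per
resistance level (chip-disjoint, so no chip-specific feature can leak).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from .chipsim import ChipStackSet, N_LEVELS

DEFAULT_SLICES = (1, 3, 5, 14, 23, 25, 27)
INPUT_SIZE = 64

__all__ = [
    "SelectedSliceSet", "NetworkInput", "DatasetSplit",
    "crop_rois", "select_slices", "to_network_input",
    "split_dataset", "build_inputs",
]


@dataclass(frozen=True)
class SelectedSliceSet:
    """1-based z indices kept for classification (default: 1,3,5,14,23,25,27)."""

    slice_indices: tuple[int, ...] = DEFAULT_SLICES
    stack_depth: int = 27

    def __post_init__(self) -> None:
        idx = self.slice_indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("slice indices must be strictly increasing")
        if not all(1 <= z <= self.stack_depth for z in idx):
            raise ValueError(f"slice indices must lie in 1..{self.stack_depth}")


@dataclass
class NetworkInput:
    """One 64x64x3 training example with its label and provenance."""

    pixels: np.ndarray  # (64, 64, 3) float in [0, 1], channels identical
    label: int
    level: int
    chip_id: str
    roi_index: int
    z_index: int


@dataclass
class DatasetSplit:
    """Train / validation / test partition; test is chip-disjoint."""

    train: list[NetworkInput]
    validation: list[NetworkInput]
    test: list[NetworkInput]
    test_chips: dict[int, str] = field(default_factory=dict)
    seed: int | None = None

    def counts(self) -> pd.DataFrame:
        """Per-level image counts in the layout of the study's dataset table."""
        rows = {}
        for name, part in [("Training", self.train), ("Validation", self.validation),
                           ("Test", self.test)]:
            rows[name] = [sum(1 for x in part if x.level == lv) for lv in range(N_LEVELS)]
        df = pd.DataFrame(rows, index=[f"Level {lv}" for lv in range(N_LEVELS)]).T
        df["Total"] = df.sum(axis=1)
        df.loc["Total"] = df.sum(axis=0)
        return df


def crop_rois(stitched_image: np.ndarray,
              layout: Sequence[tuple[int, int, int, int]]) -> list[np.ndarray]:
    """Cut the inter-pillar ROIs out of a stitched chip image.

    ``layout`` is an ordered sequence of ``(row, col, height, width)``
    rectangles; the crops are returned in layout order.
    """
    img = np.asarray(stitched_image)
    crops = []
    for k, (r, c, h, w) in enumerate(layout):
        if r < 0 or c < 0 or h <= 0 or w <= 0 or r + h > img.shape[0] or c + w > img.shape[1]:
            raise ValueError(f"ROI rectangle {k} {(r, c, h, w)} lies outside the "
                             f"stitched image of shape {img.shape}")
        crops.append(img[r:r + h, c:c + w].copy())
    return crops


def select_slices(roi_stack: np.ndarray,
                  selection: SelectedSliceSet | Sequence[int] = DEFAULT_SLICES,
                  ) -> list[tuple[int, np.ndarray]]:
    """Keep the selected z-slices (1-based) of an ROI stack, in order."""
    if not isinstance(selection, SelectedSliceSet):
        selection = SelectedSliceSet(tuple(selection), stack_depth=len(roi_stack))
    if selection.slice_indices and selection.slice_indices[-1] > len(roi_stack):
        raise ValueError("slice index exceeds stack depth")
    return [(z, roi_stack[z - 1]) for z in selection.slice_indices]


def to_network_input(roi_image: np.ndarray, label: int, *, level: int | None = None,
                     chip_id: str = "", roi_index: int = 0, z_index: int = 0,
                     size: int = INPUT_SIZE) -> NetworkInput:
    """Resize a grayscale ROI slice to ``size x size``, scale intensities to
    [0, 1] by the format's maximum, and replicate the channel three times."""
    img = np.asarray(roi_image)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel grayscale image, got shape {img.shape}")
    img = img.astype(np.float64)
    if np.issubdtype(np.asarray(roi_image).dtype, np.integer):
        img = img / np.iinfo(np.asarray(roi_image).dtype).max
    if img.shape != (size, size):
        img = resize(img, (size, size), order=1, anti_aliasing=False,
                     preserve_range=True)
    img = np.clip(img, 0.0, 1.0)
    pixels = np.repeat(img[:, :, None], 3, axis=2).astype(np.float32)
    return NetworkInput(pixels=pixels, label=int(label),
                        level=int(label if level is None else level),
                        chip_id=chip_id, roi_index=roi_index, z_index=z_index)


def build_inputs(chips: Iterable[ChipStackSet],
                 selection: SelectedSliceSet | Sequence[int] = DEFAULT_SLICES,
                 size: int = INPUT_SIZE) -> list[NetworkInput]:
    """Slice-select and convert every ROI stack of every chip."""
    inputs = []
    for chip in chips:
        for roi_idx, stack in enumerate(chip.roi_stacks):
            for z, img in select_slices(stack, selection):
                inputs.append(to_network_input(
                    img, chip.level, chip_id=chip.chip_id,
                    roi_index=roi_idx, z_index=z, size=size))
    return inputs


def split_dataset(inputs: Sequence[NetworkInput], test_chips_per_level: int = 1,
                  val_fraction: float = 0.10, seed: int = 0) -> DatasetSplit:
    """Hold out one full chip per level as the test set, then split the rest
    90/10 into training and validation per level.

    The test chip is drawn (seeded) from the chips with the most images at
    that level, so partially populated chips never serve as test.  The
    remaining images of each level are shuffled with the seed; validation
    takes ``floor(val_fraction * remaining)`` of them and training the rest.
    """
    rng = np.random.default_rng(seed)
    by_level: dict[int, list[NetworkInput]] = {lv: [] for lv in range(N_LEVELS)}
    for x in inputs:
        if x.level not in by_level:
            raise ValueError(f"level {x.level} out of range 0..3")
        by_level[x.level].append(x)

    train: list[NetworkInput] = []
    val: list[NetworkInput] = []
    test: list[NetworkInput] = []
    test_chips: dict[int, str] = {}
    for lv in range(N_LEVELS):
        pool = by_level[lv]
        chip_counts = pd.Series([x.chip_id for x in pool]).value_counts()
        if len(chip_counts) < test_chips_per_level + 1:
            raise ValueError(f"level {lv} needs at least {test_chips_per_level + 1} chips")
        full = sorted(chip_counts[chip_counts == chip_counts.max()].index)
        if len(full) < test_chips_per_level:
            raise ValueError(f"level {lv} has too few fully populated chips")
        chosen = set(rng.choice(full, size=test_chips_per_level, replace=False))
        test_chips[lv] = ",".join(sorted(chosen))
        held = [x for x in pool if x.chip_id in chosen]
        rest = [x for x in pool if x.chip_id not in chosen]
        order = rng.permutation(len(rest))
        rest = [rest[i] for i in order]
        n_val = int(np.floor(val_fraction * len(rest)))
        test.extend(held)
        val.extend(rest[:n_val])
        train.extend(rest[n_val:])
    return DatasetSplit(train=train, validation=val, test=test,
                        test_chips=test_chips, seed=seed)


def split_to_frame(split: DatasetSplit) -> pd.DataFrame:
    """Flatten a split into a manifest with a ``partition`` column."""
    rows = []
    for name, part in [("train", split.train), ("val", split.validation),
                       ("test", split.test)]:
        for x in part:
            rows.append({"level": x.level, "chip_id": x.chip_id,
                         "roi_index": x.roi_index, "z_index": x.z_index,
                         "partition": name})
    return pd.DataFrame(rows)


def stack_pixels(inputs: Sequence[NetworkInput]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a list of examples into ``(X, y)`` arrays for the network."""
    X = np.stack([x.pixels for x in inputs]).astype(np.float32)
    y = np.array([x.label for x in inputs], dtype=np.int64)
    return X, y
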