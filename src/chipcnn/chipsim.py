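"""Synthetic 3D microfluidic-chip fluorescence images with graded cell infiltration.

The generator emulates the F-actin channel of a bladder-cancer-on-a-chip
experiment: each chip carries 16 regions of interest (ROIs) between pillar
pairs, each ROI is imaged as a 27-slice z-stack, and cancer cells seeded in a
side channel infiltrate the central gel to a degree that increases with the
gemcitabine-resistance level (0..3).  Every image shows a dense cell band at
the channel edge plus a level-dependent number of infiltrating cell blobs;
slices away from the focal mid-plane are defocus-blurred.

All randomness is routed through :class:`numpy.random.Generator` streams
derived from ``(seed, chip_id, roi)`` (cell geometry, shared by all slices of
one stack) and ``(seed, chip_id, roi, z)`` (per-slice noise), so any single
slice can be re-rendered in isolation, bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure

N_LEVELS = 4

__all__ = [
    "GeneratorParams",
    "ChipStackSet",
    "render_roi",
    "generate_chip",
    "generate_dataset",
    "load_manifest",
    "quantify_infiltration",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic chip-image generator.

    ``infiltration_rate[level]`` is the expected number of infiltrating cells
    per ROI and ``infiltration_depth[level]`` their mean penetration distance
    (pixels) beyond the seeded-channel band; both are strictly increasing in
    level by default so the three morphology statistics (maximum infiltration
    distance, infiltrated area, infiltrating-cell count) grow with resistance.
    """

    roi_height_px: int = 96
    roi_width_px: int = 96
    n_rois_per_chip: int = 16
    n_slices: int = 27
    band_width_px: int = 14
    cells_baseline: float = 22.0
    infiltration_rate: tuple[float, float, float, float] = (1.0, 10.0, 25.0, 48.0)
    infiltration_depth: tuple[float, float, float, float] = (3.0, 11.0, 22.0, 35.0)
    depth_shape: float = 4.0
    band_offset_jitter_px: float = 6.0
    alternate_orientation: bool = True
    blob_radius_mean: float = 2.6
    blob_radius_sd: float = 0.5
    intensity_noise_sd: float = 0.02
    defocus_scale: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_height_px <= 0 or self.roi_width_px <= 0:
            raise ValueError("ROI dimensions must be positive")
        if self.n_rois_per_chip <= 0 or self.n_slices <= 0:
            raise ValueError("n_rois_per_chip and n_slices must be positive")
        if not (0 < self.band_width_px < self.roi_height_px):
            raise ValueError("band_width_px must lie inside the ROI height")
        if self.band_offset_jitter_px < 0 or \
                self.band_width_px + self.band_offset_jitter_px >= self.roi_height_px:
            raise ValueError("band_offset_jitter_px must be nonnegative and keep "
                             "the band inside the ROI")
        if len(self.infiltration_rate) != N_LEVELS or len(self.infiltration_depth) != N_LEVELS:
            raise ValueError("infiltration_rate/depth need one value per level 0..3")
        if any(r < 0 for r in self.infiltration_rate):
            raise ValueError("infiltration rates must be nonnegative")
        if any(d <= 0 for d in self.infiltration_depth):
            raise ValueError("infiltration depths must be positive")
        if self.blob_radius_mean <= 0:
            raise ValueError("blob_radius_mean must be positive")

    def digest(self) -> str:
        """Stable hex digest of the parameter set (provenance tag)."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def degenerate(self) -> "GeneratorParams":
        """Copy with level-independent infiltration: classes become
        statistically indistinguishable (chance-level downstream accuracy)."""
        d = asdict(self)
        d["infiltration_rate"] = (8.0,) * N_LEVELS
        d["infiltration_depth"] = (10.0,) * N_LEVELS
        return GeneratorParams(**d)


@dataclass
class ChipStackSet:
    """All images of one chip: ``roi_stacks[roi][z]`` is a 2-D float image."""

    chip_id: str
    level: int
    roi_stacks: list[np.ndarray]  # each (n_slices, H, W), values in [0, 1]
    seed: int
    params_digest: str
    flipped: bool = False  # chip mounted upside down (cell band at the bottom)

    def __post_init__(self) -> None:
        if self.level not in range(N_LEVELS):
            raise ValueError(f"level must be in 0..3, got {self.level}")


def _check_level(level: int) -> None:
    if level not in range(N_LEVELS):
        raise ValueError(f"resistance level must be an integer in 0..3, got {level!r}")


def _chip_key(chip_id: str) -> int:
    # stable across processes (unlike hash())
    return zlib.crc32(str(chip_id).encode())


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _sample_geometry(level: int, params: GeneratorParams, rng: np.random.Generator):
    """Draw the physical cell layout of one ROI: resident band cells plus
    Poisson-many infiltrating cells with gamma-distributed penetration depths."""
    H, W = params.roi_height_px, params.roi_width_px
    # per-ROI registration jitter: the channel edge never sits at exactly the
    # same row after stitching and cropping
    offset = rng.uniform(0, params.band_offset_jitter_px)
    n_band = rng.poisson(params.cells_baseline)
    rows = [offset + rng.uniform(0, params.band_width_px, size=n_band)]
    cols = [rng.uniform(0, W, size=n_band)]

    n_inf = rng.poisson(params.infiltration_rate[level])
    # gamma-distributed penetration: migration has a characteristic distance
    # (mean = infiltration_depth, cv = 1/sqrt(depth_shape))
    depths = rng.gamma(params.depth_shape,
                       params.infiltration_depth[level] / params.depth_shape,
                       size=n_inf)
    depths = np.minimum(depths, H - params.band_width_px - offset - 1)
    rows.append(offset + params.band_width_px + depths)
    cols.append(rng.uniform(0, W, size=n_inf))

    r = np.concatenate(rows)
    c = np.concatenate(cols)
    radius = np.clip(
        rng.normal(params.blob_radius_mean, params.blob_radius_sd, size=r.size),
        0.8, None,
    )
    amp = rng.uniform(0.6, 1.0, size=r.size)
    return r, c, radius, amp


def _paint_blobs(shape, rows, cols, radius, amp) -> np.ndarray:
    """Accumulate isotropic Gaussian spots; each painted only in a +-3 sigma window."""
    H, W = shape
    img = np.zeros((H, W), dtype=np.float64)
    for r0, c0, sig, a in zip(rows, cols, radius, amp):
        half = int(np.ceil(3 * sig))
        r_lo, r_hi = max(0, int(r0) - half), min(H, int(r0) + half + 1)
        c_lo, c_hi = max(0, int(c0) - half), min(W, int(c0) + half + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        img[r_lo:r_hi, c_lo:c_hi] += a * np.exp(-(rr**2 + cc**2) / (2 * sig**2))
    return img


def _render_slice(geometry, z_index: int, params: GeneratorParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Render one z-slice of a fixed cell geometry: defocus blur grows
    linearly with distance from the mid-plane, then additive Gaussian noise."""
    rows, cols, radius, amp = geometry
    img = _paint_blobs((params.roi_height_px, params.roi_width_px), rows, cols, radius, amp)
    mid = (params.n_slices + 1) / 2.0
    sigma = params.defocus_scale * abs(z_index - mid)
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma)
    if params.intensity_noise_sd > 0:
        img = img + rng.normal(0.0, params.intensity_noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def render_roi(level: int, z_index: int, params: GeneratorParams,
               rng: np.random.Generator) -> np.ndarray:
    """Render a single ROI slice.

    Draws a fresh cell geometry from ``rng`` and renders the requested
    z-slice.  Intensities lie in [0, 1]; a dense band of resident cells sits
    at the top edge (the cancer-channel side) and infiltrating blobs extend
    beyond it according to the level's rate and depth.
    """
    _check_level(level)
    if not (1 <= z_index <= params.n_slices):
        raise ValueError(
            f"z_index must be in 1..{params.n_slices} (1-based), got {z_index}")
    geometry = _sample_geometry(level, params, rng)
    return _render_slice(geometry, z_index, params, rng)


def generate_chip(level: int, chip_id: str, params: GeneratorParams,
                  seed: int | None = None, flipped: bool = False) -> ChipStackSet:
    """Generate all ROI z-stacks of one chip.

    Geometry streams are keyed by (seed, chip, roi); per-slice noise streams
    by (seed, chip, roi, z), so any slice is reproducible without
    regenerating the whole set.  ``flipped`` renders the chip mounted upside
    down: the cell band sits at the bottom edge of every ROI.
    """
    _check_level(level)
    seed = params.seed if seed is None else seed
    ck = _chip_key(chip_id)
    stacks = []
    for roi in range(params.n_rois_per_chip):
        geometry = _sample_geometry(level, params, _stream(seed, ck, roi))
        stack = np.stack([
            _render_slice(geometry, z, params, _stream(seed, ck, roi, z))
            for z in range(1, params.n_slices + 1)
        ])
        if flipped:
            stack = stack[:, ::-1, :].copy()
        stacks.append(stack)
    return ChipStackSet(chip_id=str(chip_id), level=level, roi_stacks=stacks,
                        seed=seed, params_digest=params.digest(),
                        flipped=flipped)


def generate_dataset(params: GeneratorParams, chips_per_level: int = 6,
                     level0_missing_rois: int = 2, seed: int | None = None,
                     out_dir: str | Path | None = None,
                     multipage: bool = True):
    """Generate the full synthetic study: ``chips_per_level`` chips for each
    of the four resistance levels.

    ``level0_missing_rois`` removes that many ROI stacks from level-0 chips
    other than the first chip (the first chip of each level is kept intact so
    a full chip is always available as the held-out test chip); one ROI is
    dropped from each of the last ``level0_missing_rois`` chips.  With the
    defaults (6 chips/level, 16 ROIs, 2 missing) the pool holds 94 level-0
    and 96 level-1..3 ROI stacks.

    Returns ``(manifest, chips)``; when ``out_dir`` is given, images are
    written as TIFF (one multi-page file per ROI stack, or one file per
    slice) together with ``manifest.csv`` and a ``params.json`` sidecar, and
    the manifest's ``path`` column points at the files.
    """
    if chips_per_level < 1:
        raise ValueError("chips_per_level must be >= 1")
    if level0_missing_rois < 0:
        raise ValueError("level0_missing_rois must be >= 0")
    if level0_missing_rois > max(chips_per_level - 1, 0) * params.n_rois_per_chip:
        raise ValueError("level0_missing_rois exceeds the ROIs available on non-test level-0 chips")
    seed = params.seed if seed is None else seed

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    # distribute dropped level-0 ROIs over the trailing (never-test) chips
    n_drop = [0] * chips_per_level
    i = chips_per_level - 1
    for _ in range(level0_missing_rois):
        n_drop[i] += 1
        i = i - 1 if i > 1 else chips_per_level - 1

    records = []
    chips: list[ChipStackSet] = []
    for level in range(N_LEVELS):
        for c in range(chips_per_level):
            chip_id = f"L{level}C{c}"
            # chips are mounted in alternating vertical orientation, as in a
            # study where the imaging direction is not controlled per chip
            flipped = params.alternate_orientation and c % 2 == 1
            chip = generate_chip(level, chip_id, params, seed, flipped=flipped)
            drop: set[int] = set()
            if level == 0 and n_drop[c]:
                drop = set(range(params.n_rois_per_chip - n_drop[c],
                                 params.n_rois_per_chip))
            chip.roi_stacks = [s for i_, s in enumerate(chip.roi_stacks) if i_ not in drop]
            kept_rois = [i_ for i_ in range(params.n_rois_per_chip) if i_ not in drop]
            chips.append(chip)
            for stack, roi in zip(chip.roi_stacks, kept_rois):
                stack_path = ""
                if out_path is not None and multipage:
                    stack_path = f"{chip_id}_roi{roi:02d}.tif"
                    tifffile.imwrite(out_path / stack_path,
                                     (stack * 65535).astype(np.uint16),
                                     photometric="minisblack")
                for zi in range(params.n_slices):
                    path = stack_path
                    if out_path is not None and not multipage:
                        path = f"{chip_id}_roi{roi:02d}_z{zi + 1:02d}.tif"
                        tifffile.imwrite(out_path / path,
                                         (stack[zi] * 65535).astype(np.uint16),
                                         photometric="minisblack")
                    records.append({"level": level, "chip_id": chip_id,
                                    "roi_index": roi, "z_index": zi + 1,
                                    "path": path})
    manifest = pd.DataFrame.from_records(records)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        sidecar = {"params": asdict(params), "seed": seed,
                   "params_digest": params.digest()}
        (out_path / "params.json").write_text(json.dumps(sidecar, indent=2))
    return manifest, chips


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV back into a DataFrame."""
    return pd.read_csv(Path(path) if str(path).endswith(".csv") else Path(path) / "manifest.csv")


def quantify_infiltration(image: np.ndarray, band_edge: int,
                          threshold: float) -> tuple[float, float, int]:
    """Morphology statistics of the infiltrated region beyond the band edge.

    Thresholds the image, discards the seeded-channel band (rows above
    ``band_edge``) and reports ``(max_distance, infiltrated_area,
    cell_count)``: the farthest foreground row beyond the edge (pixels), the
    foreground area (pixels^2) and the number of 8-connected components.  An
    empty foreground yields ``(0.0, 0.0, 0)``.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    fg = np.asarray(image) > threshold
    fg[:band_edge, :] = False
    if not fg.any():
        return 0.0, 0.0, 0
    rows = np.nonzero(fg.any(axis=1))[0]
    max_distance = float(rows.max() - band_edge + 1)
    area = float(fg.sum())
    n_cells = int(measure.label(fg, connectivity=2).max())
    return max_distance, area, n_cells
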