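"""Synthetic chip-image generator: determinism, geometry and graded morphology."""

import numpy as np
import pandas as pd
import pytest
from skimage import measure

from chipcnn.chipsim import (GeneratorParams, generate_chip, generate_dataset,
                             load_manifest, quantify_infiltration, render_roi)


def clean_params(**kw):
    """Noise-free, blur-free renderer so geometry is directly observable."""
    defaults = dict(roi_height_px=64, roi_width_px=64, n_rois_per_chip=2,
                    n_slices=5, intensity_noise_sd=0.0, defocus_scale=0.0, seed=3)
    defaults.update(kw)
    return GeneratorParams(**defaults)


class TestParams:
    def test_defaults_are_graded(self):
        p = GeneratorParams()
        assert all(b > a for a, b in zip(p.infiltration_rate, p.infiltration_rate[1:]))
        assert all(b > a for a, b in zip(p.infiltration_depth, p.infiltration_depth[1:]))

    @pytest.mark.parametrize("bad", [
        dict(roi_height_px=0), dict(n_slices=0), dict(band_width_px=0),
        dict(infiltration_rate=(1.0, 2.0)), dict(infiltration_depth=(1, 2, 3, 0)),
        dict(blob_radius_mean=-1.0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            GeneratorParams(**bad)

    def test_degenerate_mode_levels_identical(self):
        d = GeneratorParams().degenerate()
        assert len(set(d.infiltration_rate)) == 1
        assert len(set(d.infiltration_depth)) == 1


class TestRenderRoi:
    def test_intensities_in_unit_interval(self, rng):
        img = render_roi(2, 14, GeneratorParams(), rng)
        assert img.shape == (96, 96)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_zero_infiltration_confines_bright_pixels_to_band(self, rng):
        p = clean_params(infiltration_rate=(0.0, 1, 2, 3))
        img = render_roi(0, 3, p, rng)
        # allow registration jitter plus the soft Gaussian tail of band cells
        margin = int(np.ceil(p.band_offset_jitter_px
                             + 3 * (p.blob_radius_mean + 3 * p.blob_radius_sd)))
        assert img[p.band_width_px + margin:, :].max() < 0.05

    def test_same_seed_bit_identical(self):
        p = GeneratorParams()
        a = render_roi(1, 5, p, np.random.default_rng(11))
        b = render_roi(1, 5, p, np.random.default_rng(11))
        np.testing.assert_array_equal(a, b)

    def test_defocus_blurs_end_slices_more_than_midplane(self, rng):
        p = GeneratorParams(intensity_noise_sd=0.0, seed=5)
        mid = render_roi(3, 14, p, np.random.default_rng(5))
        end = render_roi(3, 1, p, np.random.default_rng(5))
        # same geometry (same stream) -> blur reduces the gradient energy
        assert np.abs(np.diff(end, axis=0)).sum() < np.abs(np.diff(mid, axis=0)).sum()

    @pytest.mark.parametrize("level,z", [(4, 1), (-1, 1), (0, 0), (0, 28)])
    def test_invalid_level_or_z_rejected(self, level, z, rng):
        with pytest.raises(ValueError):
            render_roi(level, z, GeneratorParams(), rng)

    def test_level3_has_more_beyond_band_blobs_than_level0(self):
        """Monte-Carlo: component counts beyond the band edge, 100 renders per
        level, independently counted with skimage connected components."""
        p = clean_params(n_rois_per_chip=1, roi_height_px=96, roi_width_px=96)
        counts = {}
        for level in (0, 3):
            rng = np.random.default_rng(42)
            n = []
            for _ in range(100):
                img = render_roi(level, 3, p, rng)
                fg = img > 0.25
                fg[:p.band_width_px + 4] = False
                n.append(measure.label(fg, connectivity=2).max())
            counts[level] = np.mean(n)
        # touching blobs merge into one component, so the observed count
        # undershoots the Poisson mean; the ordering must still be clear
        assert counts[3] > 2 * counts[0] + 3


class TestGenerateChip:
    def test_default_shape_16_rois_27_slices(self):
        p = GeneratorParams(roi_height_px=32, roi_width_px=32, seed=1)
        chip = generate_chip(2, "chipA", p)
        assert len(chip.roi_stacks) == 16
        assert all(s.shape == (27, 32, 32) for s in chip.roi_stacks)

    def test_minimal_configuration(self):
        p = clean_params(n_rois_per_chip=1, n_slices=1)
        chip = generate_chip(0, "c", p)
        assert len(chip.roi_stacks) == 1 and chip.roi_stacks[0].shape[0] == 1

    def test_different_chip_ids_differ_same_shapes(self, small_params):
        a = generate_chip(1, "A", small_params, seed=9)
        b = generate_chip(1, "B", small_params, seed=9)
        assert a.roi_stacks[0].shape == b.roi_stacks[0].shape
        assert not np.array_equal(a.roi_stacks[0], b.roi_stacks[0])

    def test_chip_regeneration_is_deterministic(self, small_params):
        a = generate_chip(3, "X", small_params, seed=2)
        b = generate_chip(3, "X", small_params, seed=2)
        for sa, sb in zip(a.roi_stacks, b.roi_stacks):
            np.testing.assert_array_equal(sa, sb)

    def test_slices_share_cell_geometry(self):
        """Slices of one ROI image the same physical cells: with no noise and
        no defocus every slice is identical."""
        chip = generate_chip(2, "c", clean_params())
        stack = chip.roi_stacks[0]
        for z in range(1, stack.shape[0]):
            np.testing.assert_array_equal(stack[0], stack[z])


class TestGenerateDataset:
    def test_default_pool_is_94_plus_3x96_roi_stacks(self, small_params):
        manifest, chips = generate_dataset(small_params, chips_per_level=6,
                                           level0_missing_rois=2, seed=7)
        stacks = manifest.groupby("level").apply(
            lambda g: len(g[["chip_id", "roi_index"]].drop_duplicates()),
            include_groups=False)
        # scaled geometry: 6 chips x 4 ROIs, minus 2 level-0 stacks
        assert stacks.tolist() == [22, 24, 24, 24]
        assert len(chips) == 24

    def test_single_chip_per_level_counts(self, small_params):
        manifest, _ = generate_dataset(small_params, chips_per_level=1,
                                       level0_missing_rois=0, seed=7)
        n_stacks = len(manifest[["level", "chip_id", "roi_index"]].drop_duplicates())
        assert n_stacks == 4 * small_params.n_rois_per_chip

    def test_excessive_missing_rois_rejected(self, small_params):
        with pytest.raises(ValueError):
            generate_dataset(small_params, chips_per_level=1, level0_missing_rois=1)

    def test_manifest_roundtrip_and_tiff_shapes(self, small_params, tmp_path):
        manifest, _ = generate_dataset(small_params, chips_per_level=1,
                                       level0_missing_rois=0, seed=7,
                                       out_dir=tmp_path)
        back = load_manifest(tmp_path / "manifest.csv")
        pd.testing.assert_frame_equal(manifest, back)
        import tifffile
        first = tifffile.imread(tmp_path / manifest.iloc[0]["path"])
        assert first.shape == (small_params.n_slices, 48, 48)
        assert first.dtype == np.uint16

    def test_regeneration_is_byte_identical(self, small_params):
        _, a = generate_dataset(small_params, chips_per_level=2, seed=3,
                                level0_missing_rois=1)
        _, b = generate_dataset(small_params, chips_per_level=2, seed=3,
                                level0_missing_rois=1)
        for ca, cb in zip(a, b):
            for sa, sb in zip(ca.roi_stacks, cb.roi_stacks):
                np.testing.assert_array_equal(sa, sb)


class TestQuantifyInfiltration:
    def test_blank_image_yields_zeros(self):
        assert quantify_infiltration(np.zeros((50, 50)), 10, 0.5) == (0.0, 0.0, 0)

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            quantify_infiltration(np.zeros((10, 10)), 2, 1.5)

    def test_single_blob_analytic_placement(self):
        """A disk of radius r centred d pixels beyond the edge: max distance
        is close to d + r and exactly one component is found."""
        edge, d, r = 20, 15, 4
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[:64, :64]
        img[(rr - (edge + d)) ** 2 + (cc - 32) ** 2 <= r ** 2] = 1.0
        max_dist, area, n = quantify_infiltration(img, edge, 0.5)
        assert n == 1
        assert abs(max_dist - (d + r)) <= 1.5
        assert abs(area - np.pi * r ** 2) / (np.pi * r ** 2) < 0.25

    def test_band_is_excluded_from_statistics(self):
        img = np.zeros((40, 40))
        img[:10] = 1.0  # bright band only
        assert quantify_infiltration(img, 10, 0.5) == (0.0, 0.0, 0)

    def test_all_three_statistics_increase_with_level(self):
        """Monte-Carlo ordering: mean (max distance, area, count) over 100
        noise-free ROIs is strictly increasing across levels 0..3."""
        p = clean_params(n_rois_per_chip=1, roi_height_px=96, roi_width_px=96)
        means = []
        for level in range(4):
            rng = np.random.default_rng(100 + level)
            stats = np.array([
                quantify_infiltration(render_roi(level, 3, p, rng),
                                      p.band_width_px, 0.2)
                for _ in range(100)])
            means.append(stats.mean(axis=0))
        means = np.array(means)
        for col in range(3):
            assert np.all(np.diff(means[:, col]) > 0), \
                f"statistic {col} not increasing: {means[:, col]}"
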