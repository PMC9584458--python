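"""Segmentation stages against brute-force oracles and ground-truth scenes."""

import numpy as np
import pytest
from scipy import signal

import holowbc as h
from holowbc.segmentation import (
    SOBEL_GX,
    SOBEL_GY,
    binarize,
    clean_mask,
    detect_edges,
    extract_green_enhanced,
    smooth_mask,
)


def michelson(channel, mask_a, mask_b):
    a, b = channel[mask_a].mean(), channel[mask_b].mean()
    return abs(a - b) / (a + b)


class TestGreenEnhanced:
    def test_pure_green_image_stretched(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0.2, 0.8, size=(60, 60))
        image = np.stack([np.zeros_like(g), g, np.zeros_like(g)], axis=2)
        out = extract_green_enhanced(image)
        lo, hi = np.percentile(g, [1, 99])
        assert np.allclose(out, np.clip((g - lo) / (hi - lo), 0, 1))

    def test_constant_image_passes_through(self):
        image = np.full((40, 40, 3), 0.5)
        assert np.allclose(extract_green_enhanced(image), 0.5)

    def test_single_channel_rejected_with_message(self):
        with pytest.raises(h.SegmentationError, match="3 channels"):
            extract_green_enhanced(np.zeros((10, 10, 1)))

    def test_stretch_increases_nucleus_contrast(self, lymph_scene):
        raw = lymph_scene.image[:, :, 1]
        enhanced = extract_green_enhanced(lymph_scene.image)
        nucleus = lymph_scene.nucleus_masks[0]
        background = ~lymph_scene.cell_masks[0]
        assert michelson(enhanced, nucleus, background) > michelson(raw, nucleus, background)


class TestBinarize:
    def test_dark_disc_recovered(self):
        yy, xx = np.mgrid[:64, :64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 < 15**2
        gray = np.where(disc, 0.3, 0.9)
        mask, i_b = binarize(gray, h.SegmentationConfig())
        # brute-force oracle: pixel-by-pixel comparison against 0.7 * I_B
        expected = np.zeros_like(disc)
        for i in range(64):
            for j in range(64):
                expected[i, j] = gray[i, j] < 0.7 * i_b
        assert i_b == pytest.approx(0.9)
        assert np.array_equal(mask, expected)
        assert np.array_equal(mask, disc)

    def test_threshold_fraction_one_keeps_everything_below_ib(self):
        rng = np.random.default_rng(5)
        gray = rng.uniform(0.1, 1.0, size=(32, 32))
        cfg = h.SegmentationConfig(threshold_fraction=1.0)
        mask, i_b = binarize(gray, cfg)
        assert np.array_equal(mask, gray < i_b)

    def test_bright_image_gives_empty_mask(self):
        mask, _ = binarize(np.full((32, 32), 0.95), h.SegmentationConfig())
        assert not mask.any()

    def test_zero_image_rejected(self):
        with pytest.raises(h.SegmentationError, match="I_B"):
            binarize(np.zeros((16, 16)))

    def test_mask_monotone_in_threshold_fraction(self):
        rng = np.random.default_rng(11)
        gray = rng.uniform(size=(48, 48))
        fractions = [0.3, 0.5, 0.7, 0.9]
        masks = [binarize(gray, h.SegmentationConfig(threshold_fraction=f))[0] for f in fractions]
        for low, high in zip(masks, masks[1:]):
            assert not (low & ~high).any()  # mask(t1) subset of mask(t2)


class TestCleanMask:
    def test_small_specks_removed_blob_kept(self):
        mask = np.zeros((400, 400), bool)
        mask[50:300, 50:300] = True  # 62500 px blob
        for r, c in [(10, 10), (10, 350), (350, 10), (350, 350), (380, 200)]:
            mask[r : r + 10, c : c + 10] = True  # five 100 px specks
        out = clean_mask(mask, h.SegmentationConfig())  # default 50000 px floor
        expected = np.zeros_like(mask)
        expected[50:300, 50:300] = True
        assert np.array_equal(out, expected)

    def test_interior_hole_filled_exactly(self):
        mask = np.zeros((300, 300), bool)
        mask[10:290, 10:290] = True
        mask[100:125, 100:120] = False  # 500 px hole
        out = clean_mask(mask, h.SegmentationConfig())
        assert out.sum() == mask.sum() + 500

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        mask = np.zeros((120, 120), bool)
        mask[20:100, 20:100] = rng.uniform(size=(80, 80)) < 0.9
        cfg = h.SegmentationConfig(min_component_px=50)
        once = clean_mask(mask, cfg)
        assert np.array_equal(clean_mask(once, cfg), once)

    def test_empty_mask_signals_no_cell(self):
        with pytest.raises(h.SegmentationError, match="no cell found"):
            clean_mask(np.zeros((64, 64), bool), h.SegmentationConfig(min_component_px=10))


class TestSmoothMask:
    def test_matches_direct_convolution_oracle(self):
        cfg = h.SegmentationConfig()
        mask = np.zeros((80, 80), bool)
        mask[20:60, 25:65] = True
        # oracle: explicit normalized Gaussian kernel, direct 2D convolution
        sigma = cfg.gaussian_window / 6.0
        x = np.arange(cfg.gaussian_window) - cfg.gaussian_window // 2
        g = np.exp(-(x**2) / (2 * sigma**2))
        kernel = np.outer(g, g)
        kernel /= kernel.sum()
        blurred = signal.convolve2d(mask.astype(float), kernel, mode="same", boundary="symm")
        assert np.array_equal(smooth_mask(mask, cfg), blurred > 0.5)

    def test_rectangle_corners_rounded_interior_unchanged(self):
        mask = np.zeros((100, 100), bool)
        mask[20:80, 20:80] = True
        out = smooth_mask(mask, h.SegmentationConfig())
        assert not out[20, 20]  # corner shaved
        assert out[28:72, 28:72].all()  # deep interior intact
        assert not out[~np.pad(mask[1:-1, 1:-1], 1)][:0].any()  # no growth far outside

    def test_all_ones_invariant(self):
        mask = np.ones((50, 50), bool)
        assert smooth_mask(mask, h.SegmentationConfig()).all()

    def test_isolated_pixel_removed(self):
        mask = np.zeros((41, 41), bool)
        mask[20, 20] = True
        assert not smooth_mask(mask, h.SegmentationConfig()).any()


class TestDetectEdges:
    def test_constant_masks_have_no_edges(self):
        assert not detect_edges(np.zeros((30, 30), bool)).any()
        assert not detect_edges(np.ones((30, 30), bool)).any()

    def test_square_outline_band(self):
        mask = np.zeros((60, 60), bool)
        mask[20:40, 20:40] = True
        edges = detect_edges(mask)
        assert edges.any()
        # every edge pixel lies within 1 px of the mask boundary
        from scipy import ndimage

        band = ndimage.binary_dilation(mask, np.ones((3, 3))) & ~ndimage.binary_erosion(
            mask, np.ones((3, 3))
        )
        assert (edges & ~band).sum() == 0
        # the band is at most 2 px wide where it crosses a mid column
        assert edges[:, 30].sum() <= 4  # two borders x band width <= 2

    def test_single_pixel_gives_eight_neighbors(self):
        mask = np.zeros((21, 21), bool)
        mask[10, 10] = True
        edges = detect_edges(mask)
        # oracle: direct 3x3 correlation of the delta with both kernels
        expected = np.zeros_like(mask)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                gx, gy = SOBEL_GX[1 - di, 1 - dj], SOBEL_GY[1 - di, 1 - dj]
                if gx != 0 or gy != 0:
                    expected[10 + di, 10 + dj] = True
        assert expected.sum() == 8
        assert np.array_equal(edges, expected)


class TestSegmentWbc:
    def test_recovers_ground_truth(self, lymph_scene, scaled_seg_cfg):
        result = h.segment_wbc(lymph_scene.image, scaled_seg_cfg)
        assert h.jaccard(result.cell_mask, lymph_scene.cell_masks[0]) >= 0.95

    def test_mask_area_monotone_in_threshold(self, lymph_scene, scaled_seg_cfg):
        from dataclasses import replace

        areas = []
        for frac in (0.55, 0.70, 0.85):
            cfg = replace(scaled_seg_cfg, threshold_fraction=frac)
            areas.append(h.segment_wbc(lymph_scene.image, cfg).cell_mask.sum())
        assert areas[0] <= areas[1] <= areas[2]

    def test_background_only_scene_raises_no_cell(self, scaled_seg_cfg):
        scene = h.render_scene([], size=(128, 128), noise_sigma=0.01, seed=0)  # noise only
        with pytest.raises(h.SegmentationError, match="no cell found"):
            h.segment_wbc(scene.image, scaled_seg_cfg)

    def test_roi_cropping(self, lymph_scene, scaled_seg_cfg):
        result = h.segment_wbc(lymph_scene.image, scaled_seg_cfg, roi=(64, 64, 128, 128))
        assert result.cell_mask.shape == (128, 128)
        assert result.roi == (64, 64, 128, 128)
        full = np.zeros((256, 256), bool)
        full[64:192, 64:192] = result.cell_mask
        assert h.jaccard(full, lymph_scene.cell_masks[0]) >= 0.90

    def test_all_five_kinds_segmented(self):
        cfg = h.SegmentationConfig().rescaled(0.1)
        for kind in h.CellKind:
            spec = h.CellSpec.for_kind(kind, center=(128, 128))
            scene = h.render_scene([spec], size=(256, 256), noise_sigma=0.0, seed=4)
            result = h.segment_wbc(scene.image, cfg)
            assert h.jaccard(result.cell_mask, scene.cell_masks[0]) >= 0.95, kind
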