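"""Quantization, maxima detection, grid localization and MAR."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_densitogram
from ctoam.densitometry import (
    GridFrame,
    LEVELS_PER_BIN,
    N_BINS,
    compute_mar,
    detect_maxima,
    level_to_bin,
    quantize,
    to_grid,
)
from ctoam.errors import ConfigError, FrameError, InputError


def _quantized(arr, window=(200.0, 1200.0), **kw):
    return quantize(make_densitogram(arr, **kw), window)


class TestQuantize:
    @pytest.mark.parametrize(
        "level,expected_bin",
        [(0, 1), (31, 1), (32, 2), (127, 4), (128, 5), (191, 6), (192, 7),
         (223, 7), (224, 8), (255, 8)],
    )
    def test_level_to_bin_boundaries(self, level, expected_bin):
        assert int(level_to_bin(level)) == expected_bin

    def test_eight_bins_of_32_levels(self):
        """All 256 8-bit values partition into exactly 8 bins of 32 levels."""
        bins = level_to_bin(np.arange(256))
        counts = np.bincount(bins, minlength=N_BINS + 1)[1:]
        assert list(counts) == [LEVELS_PER_BIN] * N_BINS

    def test_window_endpoints_and_midpoint(self):
        q = _quantized([[200.0, 1200.0, 700.0]])
        assert list(q.levels[0]) == [0, 255, 128]
        assert list(q.bins[0]) == [1, 8, 5]

    def test_out_of_window_saturates(self):
        q = _quantized([[-500.0, 5000.0]])
        assert list(q.levels[0]) == [0, 255]

    def test_zero_width_window_rejected(self):
        with pytest.raises(ConfigError):
            _quantized([[300.0]], window=(500.0, 500.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-200, 2000), min_size=2, max_size=30))
    def test_monotone_in_hu(self, hus):
        q = _quantized([sorted(hus)])
        assert np.all(np.diff(q.levels[0]) >= 0)
        assert np.all(np.diff(q.bins[0]) >= 0)


def _block_image(background_hu=300.0, block_hu=1150.0, shape=(20, 20), block=(5, 10, 5, 10)):
    arr = np.full(shape, background_hu)
    r0, r1, c0, c1 = block
    arr[r0:r1, c0:c1] = block_hu
    return arr


class TestDetectMaxima:
    def test_no_top_bin_pixels_is_empty(self):
        q = _quantized(np.full((8, 8), 300.0))
        assert detect_maxima(q) == []

    def test_single_block(self):
        q = _quantized(_block_image())
        regions = detect_maxima(q, min_area=3)
        assert len(regions) == 1
        assert regions[0].area == 25
        assert regions[0].centroid_px == pytest.approx((7.0, 7.0))
        assert regions[0].pixels.shape == (25, 2)

    def test_min_area_filters_speckles(self):
        arr = np.full((10, 10), 300.0)
        arr[2, 2] = 1150.0               # single-pixel speckle
        arr[6:9, 6:9] = 1150.0           # real 3x3 region
        q = _quantized(arr)
        regions = detect_maxima(q, min_area=3)
        assert len(regions) == 1
        assert regions[0].area == 9
        assert len(detect_maxima(q, min_area=1)) == 2

    def test_connectivity_convention(self):
        arr = np.full((6, 6), 300.0)
        arr[1, 1] = arr[2, 2] = 1150.0   # diagonal pair
        q = _quantized(arr)
        assert len(detect_maxima(q, min_area=1, connectivity=8)) == 1
        assert len(detect_maxima(q, min_area=1, connectivity=4)) == 2

    def test_peak_tracks_highest_value(self):
        arr = _block_image()
        arr[8, 9] = 1190.0
        regions = detect_maxima(_quantized(arr))
        assert regions[0].peak_px == (8.0, 9.0)


class TestGridFrame:
    def test_corners_and_center(self):
        mask = np.zeros((40, 50), dtype=bool)
        mask[10:31, 5:26] = True          # rows 10..30, cols 5..25
        frame = GridFrame.from_surface_mask(mask)
        assert frame.pixel_to_grid(10, 5) == pytest.approx((0.0, 0.0))
        assert frame.pixel_to_grid(30, 25) == pytest.approx((30.0, 30.0))
        assert frame.pixel_to_grid(20, 15) == pytest.approx((15.0, 15.0))

    def test_outside_frame_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        frame = GridFrame.from_surface_mask(mask)
        with pytest.raises(FrameError):
            frame.pixel_to_grid(0.0, 5.0)

    def test_scale_invariance(self):
        """Isotropically upscaling the densitogram leaves grid coords fixed."""
        arr = _block_image()
        q = detect_maxima(_quantized(arr))[0]
        f = GridFrame.from_surface_mask(np.isfinite(arr))
        big = np.kron(arr, np.ones((2, 2)))
        qb = detect_maxima(_quantized(big))[0]
        fb = GridFrame.from_surface_mask(np.isfinite(big))
        x1, y1 = to_grid(q, f)
        x2, y2 = to_grid(qb, fb)
        assert (x1, y1) == pytest.approx((x2, y2), abs=0.5)

    def test_empty_surface_rejected(self):
        with pytest.raises(InputError):
            GridFrame.from_surface_mask(np.zeros((5, 5), dtype=bool))


class TestMar:
    def test_ratio_definition(self):
        arr = np.full((25, 20), 300.0)    # 500 surface pixels
        arr[0:5, 0:10] = 1150.0           # 50 maximum pixels
        q = _quantized(arr)
        mar = compute_mar(detect_maxima(q), q.surface_mask)
        assert mar.mar == pytest.approx(0.10)
        assert mar.mar_pct == pytest.approx(10.0)
        assert mar.maximum_area_px == 50
        assert mar.surface_area_px == 500

    def test_no_maxima_gives_zero(self):
        q = _quantized(np.full((10, 10), 300.0))
        assert compute_mar([], q.surface_mask).mar == 0.0

    def test_empty_surface_rejected(self):
        with pytest.raises(InputError):
            compute_mar([], np.zeros((4, 4), dtype=bool))

    def test_invariant_under_translation_and_rotation(self):
        arr = _block_image(shape=(30, 24), block=(4, 12, 3, 9))
        q = _quantized(arr)
        base = compute_mar(detect_maxima(q), q.surface_mask).mar
        rolled = np.roll(arr, (5, 7), axis=(0, 1))
        rotated = np.rot90(arr)
        for variant in (rolled, rotated):
            qv = _quantized(variant)
            assert compute_mar(detect_maxima(qv), qv.surface_mask).mar == pytest.approx(base)

    def test_mar_grows_with_hotspot_size(self, quiet_spec):
        """Wider hotspots monotonically enlarge the maximum area ratio."""
        from ctoam.calibration import fit_calibration
        from ctoam.pipeline import analyze_scan
        from ctoam.projection import proximal_view
        from ctoam.synthetic import generate_volume, phantom_spec_for

        phantom = phantom_spec_for(quiet_spec)
        mars = []
        for sigma in (1.5, 2.0, 2.5, 3.0, 3.5):
            spec = replace(
                quiet_spec,
                hotspots=tuple(replace(h, sigma=sigma) for h in quiet_spec.hotspots),
            )
            vol, mask, _ = generate_volume(spec)
            fit = fit_calibration(vol, phantom)
            an = analyze_scan(vol, mask, proximal_view(), fit)
            mars.append(an.metrics.mar)
        assert np.all(np.diff(mars) > 0)
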