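"""Optical density and threshold-area quantification."""

import numpy as np
import pytest

from gelfit import GelImage, line_profile, quantify_area, quantify_od, simulate_pair
from gelfit.gaussian_fit import BackgroundModel

from conftest import make_peak, render_gaussian, seed_peaks_from_truth


class TestOpticalDensity:
    def test_od_equals_peak_height_on_noiseless_spot(self):
        pixels = render_gaussian((64, 64), 32, 32, 100.0, 3.0)
        (res,) = quantify_od(GelImage(pixels), [make_peak(32, 32)])
        assert res.od == pytest.approx(100.0)

    def test_height_ratio_depicted_exactly(self):
        pixels = render_gaussian((64, 128), 32, 32, 100.0, 3.0, background=7.0)
        pixels += render_gaussian((64, 128), 96, 32, 50.0, 3.0)
        image = GelImage(pixels)
        peaks = [make_peak(32, 32), make_peak(96, 32)]
        res = quantify_od(image, peaks, subtract_background=True, mu_bg=BackgroundModel(7.0))
        assert res[0].od / res[1].od == pytest.approx(2.0, rel=1e-9)

    def test_saturated_peaks_report_the_clip_level(self):
        pixels = render_gaussian((64, 128), 32, 32, 900.0, 3.0)
        pixels += render_gaussian((64, 128), 96, 32, 500.0, 3.0)
        clipped = np.minimum(pixels, 255.0)
        image = GelImage(clipped, saturation_level=255.0)
        res = quantify_od(image, [make_peak(32, 32), make_peak(96, 32)])
        assert res[0].od == res[1].od == 255.0


class TestLineProfile:
    def test_horizontal_profile_reads_row_values(self):
        pixels = np.tile(np.arange(32, dtype=float), (16, 1))
        prof_pos, prof_val = line_profile(
            GelImage(pixels), make_peak(4, 8), make_peak(20, 8)
        )
        np.testing.assert_allclose(prof_val, np.arange(4, 21, dtype=float))
        assert prof_pos[0] == 0.0 and prof_pos[-1] == pytest.approx(16.0)

    def test_equal_spots_valley_at_midpoint(self):
        image, _ = simulate_pair(
            "gaussian", 100, 100, 3, 3, 12.0, 0.0, seed=0, background=0, dims=(64, 64)
        )
        # true centers at x = 25.5 and 37.5 -> symmetry forces the valley at 31.5
        p, q = make_peak(26, 31), make_peak(38, 31)
        pos, vals = line_profile(image, p, q)
        assert p.x + pos[np.argmin(vals)] == pytest.approx(31.5, abs=0.5)

    def test_argmin_matches_dense_sampling_oracle(self):
        image, truth = simulate_pair(
            "gaussian", 100, 40, 4, 3, 14.0, 0.0, seed=0, background=0, dims=(80, 80)
        )
        p, q = seed_peaks_from_truth(image, truth)
        pos, vals = line_profile(image, p, q)
        coarse = pos[np.argmin(vals)]

        from scipy import ndimage

        frac = np.linspace(0, 1, int(np.hypot(q.x - p.x, q.y - p.y) * 100) + 1)
        rows = p.y + frac * (q.y - p.y)
        cols = p.x + frac * (q.x - p.x)
        dense = ndimage.map_coordinates(image.pixels, [rows, cols], order=1, mode="nearest")
        fine = frac[np.argmin(dense)] * pos[-1]
        assert coarse == pytest.approx(fine, abs=0.5)

    def test_identical_endpoints_rejected(self):
        image = GelImage(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            line_profile(image, make_peak(2, 2), make_peak(2, 2))


class TestQuantifyArea:
    def test_single_spot_volume_is_supra_threshold_sum(self):
        pixels = render_gaussian((64, 64), 32, 32, 100.0, 4.0)
        image = GelImage(pixels)
        (spot,) = quantify_area(image, [make_peak(32, 32)], threshold=10.0)
        assert spot.volume == pytest.approx(pixels[pixels > 10.0].sum())

    def test_valley_split_matches_half_plane_oracle(self):
        image, truth = simulate_pair(
            "gaussian", 100, 100, 4, 4, 14.0, 0.0, seed=0, background=0, dims=(96, 96)
        )
        p, q = seed_peaks_from_truth(image, truth)
        threshold = 10.0
        spots = quantify_area(image, [p, q], threshold)

        pos, vals = line_profile(image, p, q)
        frac = pos[np.argmin(vals)] / pos[-1]
        m = np.array([p.y + frac * (q.y - p.y), p.x + frac * (q.x - p.x)])
        direction = np.array([q.y - p.y, q.x - p.x], dtype=float)
        for spot, sign in zip(spots, (-1.0, 1.0)):
            pix = np.stack([spot.pixel_rows, spot.pixel_cols], axis=1).astype(float)
            side = (pix - m) @ direction
            assert np.all(sign * side >= 0)  # on-line pixels go to the nearer peak
        n_supra = int((image.pixels > threshold).sum())
        assert spots[0].n_pixels + spots[1].n_pixels == n_supra

    def test_monotone_profile_splits_through_q(self):
        """No valley between strongly overlapping unequal spots: the dim spot
        keeps only pixels beyond its own peak — the scheme's failure mode."""
        image, truth = simulate_pair(
            "gaussian", 100, 60, 4, 4, 8.0, 0.0, seed=0, background=0, dims=(96, 96)
        )
        p, q = seed_peaks_from_truth(image, truth)
        pos, vals = line_profile(image, p, q)
        assert np.argmin(vals) == len(vals) - 1  # profile monotone down to Q
        spots = quantify_area(image, [p, q], threshold=10.0)
        direction = np.array([q.y - p.y, q.x - p.x], dtype=float)
        m = np.array([q.y, q.x], dtype=float)
        pix_q = np.stack([spots[1].pixel_rows, spots[1].pixel_cols], axis=1).astype(float)
        assert np.all((pix_q - m) @ direction >= 0)
        assert spots[1].volume < spots[0].volume / 3  # Q grossly underestimated

    def test_disjoint_and_contained_in_region(self):
        image, truth = simulate_pair(
            "gaussian", 120, 80, 4, 3, 16.0, 0.0, seed=0, background=0, dims=(96, 96)
        )
        peaks = seed_peaks_from_truth(image, truth)
        threshold = 5.0
        spots = quantify_area(image, peaks, threshold)
        seen = set()
        for s in spots:
            coords = set(zip(s.pixel_rows.tolist(), s.pixel_cols.tolist()))
            assert not (coords & seen)
            seen |= coords
        region = set(zip(*map(list, np.nonzero(image.pixels > threshold))))
        assert seen <= region

    def test_peak_below_threshold_yields_empty_spot(self, caplog):
        pixels = render_gaussian((64, 64), 32, 32, 8.0, 3.0)
        (spot,) = quantify_area(GelImage(pixels), [make_peak(32, 32)], threshold=10.0)
        assert spot.volume == 0.0 and spot.n_pixels == 0

    def test_intensity_sweep_underestimates_small_spots(self):
        """volume/true ratio shrinks as amplitude approaches the threshold."""
        threshold, sigma = 10.0, 4.0
        ratios = []
        for mult in (20, 10, 5, 2, 1.5):
            amp = mult * threshold
            pixels = render_gaussian((128, 128), 64, 64, amp, sigma)
            (spot,) = quantify_area(GelImage(pixels), [make_peak(64, 64)], threshold)
            true = 2 * np.pi * amp * sigma**2
            ratios.append(spot.volume / true)
        assert all(a >= b for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] < 0.8
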