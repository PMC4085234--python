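"""Noise estimation, restoration kernel and peak detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gelfit import (
    DetectionParams,
    GelImage,
    NoiseEstimate,
    RestoredImage,
    compute_w_from_ipd,
    detect_peaks,
    estimate_noise,
    restoration_kernel,
    restore_image,
    simulate_pair,
)

from conftest import render_gaussian


class TestComputeW:
    @pytest.mark.parametrize("ipd,expected", [(9, 4), (10, 5), (2.0, 1), (7.9, 3)])
    def test_floor_of_half_ipd(self, ipd, expected):
        assert compute_w_from_ipd(ipd) == expected

    @pytest.mark.parametrize("ipd", [1, 1.9, 0, -3])
    def test_degenerate_ipd_rejected(self, ipd):
        with pytest.raises(ValueError):
            compute_w_from_ipd(ipd)


class TestEstimateNoise:
    def test_constant_image_has_zero_noise(self):
        image = GelImage(np.full((32, 32), 100.0))
        est = estimate_noise(image, 5)
        assert est.sigma_ns == 0.0
        assert est.n_windows_used == 0

    def test_iid_noise_sd_recovered(self, rng):
        sd = 5.0
        image = GelImage(rng.normal(0.0, sd, size=(512, 512)))
        est = estimate_noise(image, 5)
        oracle = image.pixels.std(ddof=1)
        assert est.sigma_ns == pytest.approx(oracle, rel=0.10)
        assert est.sigma_ns == pytest.approx(sd, rel=0.10)

    def test_low_mean_selection_matches_brute_force_oracle(self, rng):
        """Window selection and averaging agree with explicit enumeration."""
        pixels = rng.normal(0.0, 3.0, size=(64, 64))
        pixels[:, 32:] += 1000.0  # bright half pulls the mean of means up
        image = GelImage(pixels)
        w = 5
        est = estimate_noise(image, w)

        mus, sds = [], []
        for r in range(64 - w + 1):
            for c in range(64 - w + 1):
                win = pixels[r : r + w, c : c + w]
                mus.append(win.mean())
                sds.append(win.std(ddof=1))
        mus, sds = np.array(mus), np.array(sds)
        keep = mus < mus.mean()
        assert est.n_windows_used == keep.sum()
        assert est.sigma_ns == pytest.approx(sds[keep].mean(), abs=1e-12)

    def test_spot_windows_excluded_on_gel_like_image(self, rng):
        """A bright spot on a noisy background barely biases sigma_ns."""
        from conftest import render_gaussian

        pixels = render_gaussian((256, 256), 128, 128, 1000.0, 10.0, background=0.0)
        pixels += rng.normal(0.0, 3.0, size=pixels.shape)
        est = estimate_noise(GelImage(pixels), 5)
        assert est.sigma_ns == pytest.approx(3.0, rel=0.1)

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise(GelImage(np.zeros((3, 3))), 5)


class TestRestoration:
    @pytest.mark.parametrize("w", range(1, 21))
    def test_kernel_sums_to_zero(self, w):
        k = restoration_kernel(w)
        assert abs(k.sum()) <= 1e-12 * np.abs(k).max()

    def test_constant_image_annihilated(self):
        image = GelImage(np.full((64, 64), 123.0))
        restored = restore_image(image, 4)
        assert np.abs(restored.pixels).max() < 1e-9 * 123.0

    def test_impulse_reproduces_kernel(self):
        w = 4
        pixels = np.zeros((33, 33))
        pixels[16, 16] = 1.0
        restored = restore_image(GelImage(pixels), w)
        # symmetric kernel: convolution with a centered delta recovers K
        patch = restored.pixels[16 - w : 16 + w + 1, 16 - w : 16 + w + 1]
        np.testing.assert_allclose(patch, restoration_kernel(w), atol=1e-14)

    def test_spot_maximum_preserved_at_center(self):
        pixels = render_gaussian((64, 64), 30, 28, 100.0, 3.0, background=50.0)
        restored = restore_image(GelImage(pixels), 6)
        peak_idx = np.unravel_index(np.argmax(restored.pixels), restored.pixels.shape)
        assert peak_idx == (28, 30)


class TestDetectPeaks:
    def test_two_separated_spots_found(self):
        image, truth = simulate_pair(
            "gaussian", 1000, 1000, 3, 3, 20.0, 1.0, seed=11, background=20, dims=(96, 96)
        )
        restored = restore_image(image, 8)
        noise = estimate_noise(image, 8)
        peaks = detect_peaks(image, restored, DetectionParams(w=8, t=10), noise)
        assert len(peaks) == 2
        centers = [(s.x0, s.y0) for s in truth.spec.spots]
        for p in peaks:
            assert min(np.hypot(p.x - cx, p.y - cy) for cx, cy in centers) <= 1.0

    def test_pure_noise_rarely_yields_peaks(self):
        zero = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            image = GelImage(rng.normal(100.0, 5.0, size=(128, 128)))
            restored = restore_image(image, 5)
            noise = estimate_noise(image, 5)
            peaks = detect_peaks(image, restored, DetectionParams(w=5, t=10), noise)
            zero += not peaks
        assert zero >= 9

    def test_plateau_emits_single_peak_first_in_scan_order(self):
        pixels = np.zeros((32, 32))
        pixels[10, 14:17] = 100.0  # 3-pixel flat plateau
        image = GelImage(pixels)
        restored = RestoredImage(pixels=pixels.copy(), w=2)
        noise = NoiseEstimate(sigma_ns=0.0, n_windows_used=1)
        peaks = detect_peaks(image, restored, DetectionParams(w=2, t=10), noise)
        assert len(peaks) == 1
        assert (peaks[0].y, peaks[0].x) == (10, 14)

    def test_condition_a_matches_brute_force_disk_maximum(self, rng):
        """Dilation equality == strictly-largest-in-disk, modulo plateaus, away from borders."""
        w = 4
        pixels = rng.normal(0.0, 1.0, size=(64, 64))
        image = GelImage(pixels)
        restored = restore_image(image, w)
        # concave original: every pixel exceeds its own disk mean, so
        # condition (b) passes everywhere and only condition (a) filters
        ys, xs = np.mgrid[0:64, 0:64].astype(float)
        concave = GelImage(1e6 - 0.01 * ((xs - 32) ** 2 + (ys - 32) ** 2))
        peaks = detect_peaks(
            concave, restored, DetectionParams(w=w, t=1e-12), NoiseEstimate(0.0, 1)
        )
        got = {(p.y, p.x) for p in peaks if w <= p.y < 64 - w and w <= p.x < 64 - w}

        ares = restored.pixels
        expected = set()
        for y in range(w, 64 - w):
            for x in range(w, 64 - w):
                window = [
                    ares[y + i, x + j]
                    for i in range(-w, w + 1)
                    for j in range(-w, w + 1)
                    if i**2 + j**2 <= w**2 and (i, j) != (0, 0)
                ]
                if ares[y, x] > max(window):
                    expected.add((y, x))
        # continuous noise: plateaus have probability zero
        assert got == expected

    def test_detection_scale_equivariant(self, rng):
        image, _ = simulate_pair(
            "gaussian", 500, 300, 3, 3, 18.0, 2.0, seed=5, background=10, dims=(80, 80)
        )
        w, t = 7, 10.0
        noise = estimate_noise(image, w)
        base = detect_peaks(image, restore_image(image, w), DetectionParams(w=w, t=t), noise)
        lam = 37.5
        scaled = GelImage(image.pixels * lam)
        noise_scaled = NoiseEstimate(sigma_ns=noise.sigma_ns * lam, n_windows_used=noise.n_windows_used)
        rescaled = detect_peaks(
            scaled, restore_image(scaled, w), DetectionParams(w=w, t=t), noise_scaled
        )
        assert [(p.x, p.y) for p in base] == [(p.x, p.y) for p in rescaled]

    def test_w_mismatch_rejected(self):
        image = GelImage(np.zeros((16, 16)))
        restored = restore_image(image, 3)
        with pytest.raises(ValueError):
            detect_peaks(image, restored, DetectionParams(w=4), NoiseEstimate(0.0, 1))


@given(st.floats(min_value=2.0, max_value=1000.0))
def test_w_from_ipd_is_a_usable_radius(ipd):
    w = compute_w_from_ipd(ipd)
    assert 1 <= w <= ipd / 2 < w + 1
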