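"""Noise estimation, image restoration and peak detection.

The detection stage works on a *restored* image: the original raster
convolved with a zero-sum kernel that combines Gaussian noise smoothing
with subtraction of a boxcar-estimated local background. Peaks are
pixels that are (a) maximal within a disk of radius ``w`` on the
restored image and (b) brighter than a noise-derived threshold on the
original image.

``w`` is the single scale parameter of the detector: it should be
smaller than the smallest inter-peak distance (IPD) of spots that must
be resolved, but large enough that one spot cannot carry two peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .image import GelImage

__all__ = [
    "DetectionParams",
    "NoiseEstimate",
    "RestoredImage",
    "Peak",
    "compute_w_from_ipd",
    "estimate_noise",
    "restoration_kernel",
    "restore_image",
    "detect_peaks",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detector settings.

    ``w`` is the dilation radius / window half-width in pixels; ``t``
    scales the noise SD into the intensity threshold of condition (b).
    ``t = 10`` is a robust default for real 2-DE images; smaller values
    admit more false positives, larger values more false negatives.
    """

    w: int
    t: float = 10.0

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("w must be >= 1 pixel")
        if not self.t > 0:
            raise ValueError("t must be positive")


@dataclass(frozen=True)
class NoiseEstimate:
    """Standard deviation of the background image noise (sigma_ns)."""

    sigma_ns: float
    n_windows_used: int

    def __post_init__(self) -> None:
        if self.sigma_ns < 0:
            raise ValueError("sigma_ns must be non-negative")


@dataclass(frozen=True)
class RestoredImage:
    """Background-subtracted, noise-smoothed image used only for peak detection."""

    pixels: np.ndarray
    w: int


@dataclass(frozen=True)
class Peak:
    """A detected local maximum. ``x`` is the column, ``y`` the row (0-based)."""

    x: int
    y: int
    restored_intensity: float
    original_intensity: float


def compute_w_from_ipd(ipd: float) -> int:
    """Derive the detection scale ``w`` from the smallest inter-peak distance.

    ``w = floor(ipd / 2)``: the largest integer radius guaranteed not to
    merge the two closest resolvable spots.
    """
    if ipd <= 0:
        raise ValueError("ipd must be positive")
    w = math.floor(ipd / 2)
    if w < 1:
        raise ValueError(f"ipd={ipd} yields w={w}; w must be at least 1 pixel")
    return w


def estimate_noise(image: GelImage, w: int, *, tiled: bool = False) -> NoiseEstimate:
    """Estimate the background noise SD from low-mean ``w`` x ``w`` windows.

    The image is covered with ``w`` x ``w`` windows (sliding with full
    support by default; non-overlapping tiles with ``tiled=True``). For
    each window the mean and SD of its pixels are computed. Windows
    whose mean lies strictly below the mean of all window means are
    taken as background — most of a gel image is background, so spot
    windows pull the global mean up and are excluded — and sigma_ns is
    the average SD over those background windows.

    A constant image has no window below the mean of means and returns
    ``sigma_ns = 0`` with ``n_windows_used = 0``.
    """
    if w < 2:
        raise ValueError("noise estimation needs w >= 2")
    a = image.pixels
    if a.shape[0] < w or a.shape[1] < w:
        raise ValueError(f"image {a.shape} smaller than {w}x{w} noise window")

    windows = sliding_window_view(a, (w, w))
    if tiled:
        windows = windows[::w, ::w]
    flat = windows.reshape(-1, w * w)
    mu_area = flat.mean(axis=1)
    sigma_area = flat.std(axis=1, ddof=1)

    background = mu_area < mu_area.mean()
    n_used = int(background.sum())
    if n_used == 0:
        return NoiseEstimate(sigma_ns=0.0, n_windows_used=0)
    return NoiseEstimate(sigma_ns=float(sigma_area[background].mean()), n_windows_used=n_used)


def restoration_kernel(w: int, smooth_sd: float = 2.0, scale: float = 1.0) -> np.ndarray:
    """Zero-sum kernel combining Gaussian smoothing and boxcar background removal.

    Over the support i, j in [-w, w] the kernel is
    ``scale * (G(i, j) - 1 / (2w + 1)^2)`` where ``G`` is an isotropic
    Gaussian of SD ``smooth_sd`` normalized to unit sum over the
    support. Convolving with it equals smoothing the image and
    subtracting a boxcar local-background estimate in one pass. Because
    peak detection compares the restored image only against its own
    dilation, detections are invariant to the positive ``scale``.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    if smooth_sd <= 0 or scale <= 0:
        raise ValueError("smooth_sd and scale must be positive")
    idx = np.arange(-w, w + 1, dtype=float)
    g1 = np.exp(-(idx**2) / (2.0 * smooth_sd**2))
    g = np.outer(g1, g1)
    g /= g.sum()
    boxcar = 1.0 / (2 * w + 1) ** 2
    return scale * (g - boxcar)


def restore_image(
    image: GelImage,
    w: int,
    *,
    smooth_sd: float = 2.0,
    mode: str = "reflect",
) -> RestoredImage:
    """Convolve the image with the zero-sum restoration kernel.

    The restored image is the basis for peak detection only; model
    fitting always uses the original image. ``mode`` selects boundary
    handling ('reflect' keeps edges artifact-free; 'constant' gives
    zero padding).
    """
    k = restoration_kernel(w, smooth_sd=smooth_sd)
    restored = ndimage.convolve(image.pixels, k, mode=mode)
    return RestoredImage(pixels=restored, w=w)


def _disk_footprint(radius: int) -> np.ndarray:
    idx = np.arange(-radius, radius + 1)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    return (ii**2 + jj**2) <= radius**2


def detect_peaks(
    image: GelImage,
    restored: RestoredImage,
    params: DetectionParams,
    noise: NoiseEstimate,
    *,
    mode: str = "reflect",
) -> list[Peak]:
    """Detect spot peaks on the restored image.

    A pixel is a peak when

    a) its restored value equals the grayscale dilation of the restored
       image with a flat disk of radius ``w`` (i.e. it is the brightest
       restored pixel within distance ``w``), and
    b) its *original* intensity exceeds ``mu_w + t * sigma_ns`` where
       ``mu_w`` is the mean original intensity over the same disk.

    If several connected pixels form a plateau of equal maximal restored
    value, a single peak is emitted at the plateau pixel that comes
    first in row-major scan order. Peaks are returned sorted by
    descending original intensity.
    """
    if restored.w != params.w:
        raise ValueError(
            f"restored image built with w={restored.w} but detection uses w={params.w}"
        )
    w, t = params.w, params.t
    a = image.pixels
    ares = restored.pixels
    footprint = _disk_footprint(w)

    dilated = ndimage.grey_dilation(ares, footprint=footprint, mode=mode)
    candidates = ares == dilated

    # one peak per connected plateau (8-connectivity), first in scan order
    labels, n_labels = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    peak_mask = np.zeros_like(candidates)
    if n_labels:
        flat_first = ndimage.minimum(
            np.arange(a.size).reshape(a.shape), labels, index=np.arange(1, n_labels + 1)
        )
        peak_mask.flat[np.asarray(flat_first, dtype=int)] = True

    # condition (b): local mean of the ORIGINAL image over the disk
    mu_w = ndimage.correlate(a, footprint / footprint.sum(), mode=mode)
    threshold = mu_w + t * noise.sigma_ns
    peak_mask &= a > threshold

    ys, xs = np.nonzero(peak_mask)
    peaks = [
        Peak(x=int(x), y=int(y), restored_intensity=float(ares[y, x]), original_intensity=float(a[y, x]))
        for y, x in zip(ys, xs)
    ]
    peaks.sort(key=lambda p: -p.original_intensity)
    return peaks
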