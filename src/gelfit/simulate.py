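"""Synthetic gel images with exact ground truth.

The simulator renders spot surfaces on a flat background, adds i.i.d.
Gaussian read noise and optionally clips at a saturation level. Three
radially symmetric spot shapes are available:

``gaussian``
    I * exp(-0.5 r^2 / sigma^2); the shape the fitting model assumes.
    Its true signal is the closed-form volume 2 pi I sigma^2.
``lorentz``
    I / (1 + r^2 / s^2); heavier tails than any Gaussian. Its 2-D
    integral diverges, so the *true signal is defined as the noiseless
    rendered sum over the image support*. Ratios of such signals are
    well defined for spots rendered on the same support.
``diffusion``
    a uniform disk of radius R blurred by an isotropic Gaussian of SD D
    (out-diffusion of an initially sharp spot), scaled to peak
    amplitude I. The profile is computed by stable radial quadrature;
    true signal is again the noiseless rendered sum.

SNR is defined throughout as peak amplitude over noise SD, I / noise_sd.
Surfaces are sampled at pixel centers (no within-pixel integration);
spots at gel scales are smooth enough that this is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e

from .image import GelImage

__all__ = [
    "SpotSpec",
    "SceneSpec",
    "SceneTruth",
    "render_scene",
    "simulate_pair",
    "simulate_field",
]

SHAPES = ("gaussian", "lorentz", "diffusion")


@dataclass(frozen=True)
class SpotSpec:
    """One spot: shape, subpixel center (x0, y0), peak amplitude and width.

    ``width`` is sigma for gaussian, the half-width s for lorentz, and
    the pair (R, D) — disk radius and blur SD — for diffusion spots.
    """

    shape: str
    x0: float
    y0: float
    amplitude: float
    width: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown spot shape {self.shape!r}; use one of {SHAPES}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        widths = self.width if isinstance(self.width, tuple) else (self.width,)
        if self.shape == "diffusion" and len(widths) != 2:
            raise ValueError("diffusion spots need width=(R, D)")
        if self.shape != "diffusion" and len(widths) != 1:
            raise ValueError(f"{self.shape} spots take a scalar width")
        if any(v <= 0 for v in widths):
            raise ValueError("width parameters must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic image; (spec, seed) -> image is pure."""

    shape: tuple[int, int]  # (height, width)
    background: float
    spots: tuple[SpotSpec, ...]
    noise_sd: float = 0.0
    saturation_level: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError("image dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "spots", tuple(self.spots))


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for a rendered scene.

    ``true_signals[i]`` is the exact signal of ``spec.spots[i]``:
    2 pi I sigma^2 for gaussian spots, the noiseless rendered sum over
    the image support for lorentz and diffusion spots.
    """

    spec: SceneSpec
    true_signals: tuple[float, ...]

    def true_ratio(self, i: int = 0, j: int = 1) -> float:
        return self.true_signals[i] / self.true_signals[j]


def _diffusion_profile(r: np.ndarray, R: float, D: float) -> np.ndarray:
    """Unit-disk (radius R) convolved with a Gaussian of SD D, at radii r.

    p(r) = int_0^R (s / D^2) exp(-(s - r)^2 / (2 D^2)) i0e(r s / D^2) ds,
    using the exponentially scaled Bessel function for stability; the
    peak value is p(0) = 1 - exp(-R^2 / (2 D^2)).
    """
    s = np.linspace(0.0, R, 2048)
    rr = np.atleast_1d(r).astype(float)[:, None]
    integrand = (s / D**2) * np.exp(-((s - rr) ** 2) / (2 * D**2)) * i0e(rr * s / D**2)
    return np.trapezoid(integrand, s, axis=1)


def _spot_surface(spot: SpotSpec, shape: tuple[int, int]) -> np.ndarray:
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r2 = (xs - spot.x0) ** 2 + (ys - spot.y0) ** 2
    if spot.shape == "gaussian":
        return spot.amplitude * np.exp(-0.5 * r2 / spot.width**2)
    if spot.shape == "lorentz":
        return spot.amplitude / (1.0 + r2 / spot.width**2)
    R, D = spot.width
    r_max = float(np.sqrt(r2.max()))
    # radial lookup table, then per-pixel interpolation
    r_grid = np.linspace(0.0, r_max, 2048)
    profile = _diffusion_profile(r_grid, R, D)
    peak = profile[0]
    surface = np.interp(np.sqrt(r2).ravel(), r_grid, profile).reshape(shape)
    return spot.amplitude * surface / peak


def render_scene(spec: SceneSpec) -> tuple[GelImage, SceneTruth]:
    """Render a scene and return the image with its exact ground truth."""
    h, w = spec.shape
    for spot in spec.spots:
        if not (0 <= spot.x0 < w and 0 <= spot.y0 < h):
            raise ValueError(f"spot center ({spot.x0}, {spot.y0}) outside {w}x{h} image")

    noiseless = np.full(spec.shape, spec.background, dtype=float)
    true_signals = []
    for spot in spec.spots:
        surface = _spot_surface(spot, spec.shape)
        noiseless += surface
        if spot.shape == "gaussian":
            true_signals.append(2.0 * np.pi * spot.amplitude * spot.width**2)
        else:
            true_signals.append(float(surface.sum()))

    pixels = noiseless
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    if spec.saturation_level is not None:
        pixels = np.minimum(pixels, spec.saturation_level)

    image = GelImage(pixels=pixels, saturation_level=spec.saturation_level)
    return image, SceneTruth(spec=spec, true_signals=tuple(true_signals))


def simulate_pair(
    shape: str,
    I_P: float,
    I_Q: float,
    width_P: float | tuple[float, float],
    width_Q: float | tuple[float, float],
    ipd: float,
    noise_sd: float,
    seed: int,
    *,
    dims: tuple[int, int] | None = None,
    background: float = 0.0,
    saturation_level: float | None = None,
) -> tuple[GelImage, SceneTruth]:
    """Two spots P and Q on a horizontal line, ``ipd`` pixels apart.

    The pair is centered in the image; ``dims`` defaults to a square
    comfortably holding both spots (ipd plus 12 widths of margin).
    """
    if ipd <= 0:
        raise ValueError("ipd must be positive")
    wP = max(width_P) if isinstance(width_P, tuple) else width_P
    wQ = max(width_Q) if isinstance(width_Q, tuple) else width_Q
    if dims is None:
        side = int(np.ceil(ipd + 12 * max(wP, wQ)))
        side += side % 2  # even side keeps the pair centered on a half-integer
        dims = (side, side)
    cy = (dims[0] - 1) / 2.0
    cx = (dims[1] - 1) / 2.0
    spots = (
        SpotSpec(shape=shape, x0=cx - ipd / 2.0, y0=cy, amplitude=I_P, width=width_P),
        SpotSpec(shape=shape, x0=cx + ipd / 2.0, y0=cy, amplitude=I_Q, width=width_Q),
    )
    spec = SceneSpec(
        shape=dims,
        background=background,
        spots=spots,
        noise_sd=noise_sd,
        saturation_level=saturation_level,
        seed=seed,
    )
    return render_scene(spec)


def simulate_field(
    n_spots: int,
    amplitude_range: tuple[float, float],
    sigma_range: tuple[float, float],
    min_ipd: float,
    dims: tuple[int, int],
    noise_sd: float,
    seed: int,
    *,
    background: float = 0.0,
    margin: float | None = None,
    max_tries: int = 10_000,
) -> tuple[GelImage, SceneTruth]:
    """A field of Gaussian spots with random parameters and a minimum spacing.

    Centers are drawn by rejection sampling so every pairwise distance
    is at least ``min_ipd``; amplitudes and widths are uniform over the
    given ranges. ``margin`` keeps centers away from the border
    (default: 4 * max sigma). Raises when the requested density cannot
    be placed within ``max_tries`` draws.
    """
    if n_spots < 1:
        raise ValueError("need at least one spot")
    rng = np.random.default_rng(seed)
    if margin is None:
        margin = 4.0 * sigma_range[1]
    h, w = dims
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("image too small for the requested margin")

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_spots:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_spots} spots with min_ipd={min_ipd} in {dims} "
                f"after {max_tries} draws; reduce the density"
            )
        tries += 1
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        if all(np.hypot(x - cx, y - cy) >= min_ipd for cx, cy in centers):
            centers.append((x, y))

    spots = tuple(
        SpotSpec(
            shape="gaussian",
            x0=cx,
            y0=cy,
            amplitude=rng.uniform(*amplitude_range),
            width=rng.uniform(*sigma_range),
        )
        for cx, cy in centers
    )
    spec = SceneSpec(
        shape=dims,
        background=background,
        spots=spots,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return render_scene(spec)
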