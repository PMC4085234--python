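"""Compound fitting of circular 2-D Gaussians and spot quantification.

Each compound is fitted independently on its own pixels: the model is a
sum of circular Gaussians, one per detected peak,

    f(x, y) = sum_j I_j * exp(-0.5 * ((x - x0_j)^2 + (y - y0_j)^2) / sigma_j^2) + mu_bg

with the mean background level mu_bg computed beforehand from all pixels
outside every compound area and held fixed during the fit. Fitting is
always performed on the original image, never on the restored one.

The spot signal is the volume under the fitted surface,
VUS = 2 pi I sigma^2, which is proportional to the number of photons
collected and hence to protein amount. Fits with sigma <= 1 pixel are
flagged as false positives: single-pixel camera noise produces peaks
without a broad base, and no real spot is that narrow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .compounding import Compound
from .detection import Peak
from .image import GelImage

__all__ = [
    "BackgroundModel",
    "SpotFit",
    "estimate_background",
    "fit_compound",
    "fit_all_compounds",
    "compute_vus",
    "discard_false_positives",
    "render_model",
]

logger = logging.getLogger(__name__)

#: fits with sigma at or below this width (pixels) are flagged as false positives
FALSE_POSITIVE_SIGMA = 1.0


@dataclass(frozen=True)
class BackgroundModel:
    """Mean background intensity mu_bg, estimated outside all compound areas."""

    mu_bg: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu_bg):
            raise ValueError("mu_bg must be finite")


@dataclass(frozen=True)
class SpotFit:
    """Fitted parameters of one spot.

    ``vus`` is derived, never stored: 2 pi I sigma^2.
    """

    peak_id: int
    compound_id: int
    x0: float
    y0: float
    I: float
    sigma: float
    converged: bool
    residual_norm: float
    discarded: bool = False

    def __post_init__(self) -> None:
        if self.I < 0:
            raise ValueError("amplitude I must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def vus(self) -> float:
        return compute_vus(self.I, self.sigma)


def estimate_background(image: GelImage, compounds: list[Compound]) -> BackgroundModel:
    """Mean intensity over all pixels outside every compound area.

    Compound areas enclose everything carrying spot signal, so the
    remaining pixels are pure background.
    """
    outside = np.ones(image.shape, dtype=bool)
    for c in compounds:
        outside &= ~c.mask
    if not outside.any():
        raise ValueError(
            "compound areas cover the whole image; reduce d so background pixels remain"
        )
    return BackgroundModel(mu_bg=float(image.pixels[outside].mean()))


def compute_vus(I: float, sigma: float) -> float:
    """Volume under a circular Gaussian surface: 2 pi I sigma^2."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 2.0 * math.pi * I * sigma**2


def _gaussian_sum(params: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    model = np.zeros_like(xs, dtype=float)
    for j in range(params.size // 4):
        x0, y0, amp, sigma = params[4 * j : 4 * j + 4]
        r2 = (xs - x0) ** 2 + (ys - y0) ** 2
        model += amp * np.exp(-0.5 * r2 / sigma**2)
    return model


def fit_compound(
    image: GelImage,
    compound: Compound,
    peaks: list[Peak],
    mu_bg: BackgroundModel,
    *,
    compound_id: int = 0,
    w: int = 4,
    d: int | None = None,
    fit_background: bool = False,
    max_nfev_per_param: int = 200,
) -> list[SpotFit]:
    """Fit a sum of circular Gaussians plus mu_bg to one compound.

    All spots of the compound are fitted simultaneously over the
    compound-area pixels of the *original* image, 4 parameters per spot
    (x0, y0, I, sigma). mu_bg stays fixed unless ``fit_background`` is
    set. Saturated pixels (at or above ``image.saturation_level``) are
    censored from the residual. Optimizer failures are reported through
    ``converged=False``, never raised.

    Initialization: centers at the detected peak pixels, amplitudes at
    the peak intensity above background, sigma at ``max(1.5, w / 2)``.
    Bounds: I >= 0; sigma in (0.1, d]; centers within the compound
    bounding box expanded by ``w``.
    """
    if not compound.peak_ids:
        raise ValueError("compound has no peaks")
    rows, cols = compound.pixel_coords()
    if rows.size == 0:
        raise ValueError("compound mask is empty")

    if d is None:
        d = int(max(rows.max() - rows.min(), cols.max() - cols.min()) + 1)

    values = image.pixels[rows, cols]
    keep = np.ones(rows.size, dtype=bool)
    if image.saturation_level is not None:
        keep = values < image.saturation_level
        if not keep.any():
            keep = np.ones(rows.size, dtype=bool)  # fully clipped: fit anyway
    xs = cols[keep].astype(float)
    ys = rows[keep].astype(float)
    data = values[keep]

    members = [peaks[i] for i in compound.peak_ids]
    k = len(members)
    sigma0 = max(1.5, w / 2.0)
    x_lo, x_hi = cols.min() - w, cols.max() + w
    y_lo, y_hi = rows.min() - w, rows.max() + w

    p0, lo, hi = [], [], []
    for p in members:
        amp0 = max(p.original_intensity - mu_bg.mu_bg, 1e-6)
        p0 += [float(p.x), float(p.y), amp0, sigma0]
        lo += [x_lo, y_lo, 0.0, 0.1]
        hi += [x_hi, y_hi, np.inf, float(d)]
    if fit_background:
        p0.append(mu_bg.mu_bg)
        lo.append(-np.inf)
        hi.append(np.inf)

    def residuals(params: np.ndarray) -> np.ndarray:
        if fit_background:
            bg = params[-1]
            params = params[:-1]
        else:
            bg = mu_bg.mu_bg
        return _gaussian_sum(params, xs, ys) + bg - data

    try:
        result = least_squares(
            residuals,
            np.asarray(p0),
            bounds=(np.asarray(lo), np.asarray(hi)),
            method="trf",
            ftol=1e-8,
            xtol=1e-8,
            max_nfev=max_nfev_per_param * (4 * k + int(fit_background)),
        )
        params = result.x[:-1] if fit_background else result.x
        converged = bool(result.status > 0)
        cost = float(2.0 * result.cost)
    except Exception:  # pragma: no cover - defensive; least_squares rarely raises
        logger.warning("optimizer failed on compound %d; keeping initial guess", compound_id)
        params = np.asarray(p0[: 4 * k])
        converged = False
        cost = float(np.sum(residuals(np.asarray(p0)) ** 2))

    if not converged:
        logger.warning("fit of compound %d did not converge", compound_id)

    fits = []
    for j, peak_idx in enumerate(compound.peak_ids):
        x0, y0, amp, sigma = params[4 * j : 4 * j + 4]
        fits.append(
            SpotFit(
                peak_id=peak_idx,
                compound_id=compound_id,
                x0=float(x0),
                y0=float(y0),
                I=float(amp),
                sigma=float(sigma),
                converged=converged,
                residual_norm=cost,
            )
        )
    return fits


def fit_all_compounds(
    image: GelImage,
    compounds: list[Compound],
    peaks: list[Peak],
    mu_bg: BackgroundModel,
    *,
    w: int = 4,
    d: int | None = None,
    fit_background: bool = False,
) -> list[SpotFit]:
    """Fit every compound sequentially and flag false positives."""
    fits: list[SpotFit] = []
    for cid, compound in enumerate(compounds):
        fits.extend(
            fit_compound(
                image,
                compound,
                peaks,
                mu_bg,
                compound_id=cid,
                w=w,
                d=d,
                fit_background=fit_background,
            )
        )
    return discard_false_positives(fits)


def discard_false_positives(fits: list[SpotFit]) -> list[SpotFit]:
    """Flag (never remove) fits whose sigma is at most one pixel."""
    return [replace(f, discarded=f.sigma <= FALSE_POSITIVE_SIGMA) for f in fits]


def render_model(
    shape: tuple[int, int], fits: list[SpotFit], mu_bg: BackgroundModel | float = 0.0
) -> np.ndarray:
    """Evaluate the fitted model surface over a full image grid.

    Discarded fits are excluded. Used for the reconstructed-model and
    residual images.
    """
    bg = mu_bg.mu_bg if isinstance(mu_bg, BackgroundModel) else float(mu_bg)
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    model = np.full(shape, bg, dtype=float)
    for f in fits:
        if f.discarded:
            continue
        r2 = (xs - f.x0) ** 2 + (ys - f.y0) ** 2
        model += f.I * np.exp(-0.5 * r2 / f.sigma**2)
    return model
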