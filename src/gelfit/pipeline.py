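"""End-to-end pipeline: noise -> restoration -> peaks -> compounds -> fit.

Mirrors the processing order of the detection/quantification algorithm:

1. estimate the background-noise SD sigma_ns,
2. restore the image (smooth + local-background subtraction),
3. detect peaks on the restored image,
4. group peaks into fitting compounds,
5. estimate the global background mu_bg outside compound areas,
6. fit all compounds on the original image and flag false positives.

Every stage logs its parameters and counts so runs are auditable. The
pipeline is deterministic given image and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .comparators import quantify_area, quantify_od
from .compounding import Compound, group_peaks
from .detection import (
    DetectionParams,
    NoiseEstimate,
    Peak,
    compute_w_from_ipd,
    detect_peaks,
    estimate_noise,
    restore_image,
)
from .gaussian_fit import (
    BackgroundModel,
    SpotFit,
    estimate_background,
    fit_all_compounds,
    render_model,
)
from .image import GelImage

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_outputs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters for one pipeline run.

    Exactly one of ``ipd`` / ``w`` must be given; ``d`` defaults to
    ``6 * w`` (a +-3 sigma compound area for spots with sigma <= w).
    """

    ipd: float | None = None
    w: int | None = None
    t: float = 10.0
    d: int | None = None
    fit_background: bool = False
    area_threshold: float | None = None  # None: mu_bg + t * sigma_ns

    def __post_init__(self) -> None:
        if (self.ipd is None) == (self.w is None):
            raise ValueError("exactly one of ipd / w must be provided")
        if self.w is not None and self.w < 1:
            raise ValueError("w must be >= 1")
        if self.ipd is not None and self.ipd <= 0:
            raise ValueError("ipd must be positive")
        if self.t <= 0:
            raise ValueError("t must be positive")
        if self.d is not None and self.d < 1:
            raise ValueError("d must be >= 1")

    def resolved_w(self) -> int:
        return self.w if self.w is not None else compute_w_from_ipd(self.ipd)

    def resolved_d(self) -> int:
        return self.d if self.d is not None else 6 * self.resolved_w()


@dataclass(frozen=True)
class PipelineResult:
    """Everything one pipeline run produced."""

    image: GelImage
    noise: NoiseEstimate
    peaks: list[Peak]
    compounds: list[Compound]
    mu_bg: BackgroundModel
    fits: list[SpotFit]
    w: int
    d: int


def run_pipeline(image: GelImage, config: RunConfig) -> PipelineResult:
    """Run detection, compounding and compound fitting on one image."""
    w = config.resolved_w()
    d = config.resolved_d()

    noise = estimate_noise(image, w)
    logger.info("noise: sigma_ns=%.6g from %d windows (w=%d)", noise.sigma_ns, noise.n_windows_used, w)

    restored = restore_image(image, w)
    params = DetectionParams(w=w, t=config.t)
    peaks = detect_peaks(image, restored, params, noise)
    logger.info("detection: %d peaks (w=%d, t=%g)", len(peaks), w, config.t)

    compounds = group_peaks(peaks, d, image.shape)
    logger.info("compounding: %d compounds (d=%d)", len(compounds), d)

    mu_bg = estimate_background(image, compounds)
    logger.info("background: mu_bg=%.6g", mu_bg.mu_bg)

    fits = fit_all_compounds(
        image, compounds, peaks, mu_bg, w=w, d=d, fit_background=config.fit_background
    )
    n_discarded = sum(f.discarded for f in fits)
    n_failed = sum(not f.converged for f in fits)
    logger.info("fit: %d spots, %d discarded, %d not converged", len(fits), n_discarded, n_failed)
    if any(f.sigma > d / 6.0 for f in fits if not f.discarded):
        logger.warning("a fitted sigma exceeds d/6=%g; consider a larger d", d / 6.0)

    return PipelineResult(
        image=image, noise=noise, peaks=peaks, compounds=compounds,
        mu_bg=mu_bg, fits=fits, w=w, d=d,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path, config: RunConfig) -> None:
    """Write spots.csv, signals.csv and the model/residual TIFFs."""
    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    io.write_peaks(out / "peaks.csv", result.peaks)
    io.write_compounds(
        out / "compounds.csv", result.peaks, result.compounds,
        mask_json_path=out / "compound_masks.json",
    )
    io.write_spots(out / "spots.csv", result.fits, result.mu_bg.mu_bg)

    threshold = (
        config.area_threshold
        if config.area_threshold is not None
        else result.mu_bg.mu_bg + config.t * result.noise.sigma_ns
    )
    od = quantify_od(result.image, result.peaks)
    area = quantify_area(result.image, result.peaks, threshold)
    io.write_signals(
        out / "signals.csv",
        [
            io.signals_to_frame("fit", result.fits),
            io.signals_to_frame("od", od),
            io.signals_to_frame("area", area),
        ],
    )

    model = render_model(result.image.shape, result.fits, result.mu_bg)
    io.write_image(out / "model.tif", model)
    io.write_image(out / "residual.tif", result.image.pixels - model)
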