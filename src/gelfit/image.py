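"""Core image container for gel / immunoblot rasters.

All processing operates on a single-channel floating-point raster.
Coordinates follow the (row = y, col = x), 0-based convention; pixel
centers sit on integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GelImage:
    """A single-channel gel image in arbitrary densitometric units.

    Parameters
    ----------
    pixels
        2-D float array of intensities.
    saturation_level
        Intensity at which the acquiring camera clips, if known. When
        set, saturated pixels can be censored during model fitting.
    """

    pixels: np.ndarray
    saturation_level: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"gel image must be 2-D, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("gel image must have at least one pixel")
        if not np.all(np.isfinite(px)):
            raise ValueError("gel image contains non-finite pixel values")
        if self.saturation_level is not None and np.any(px > self.saturation_level):
            raise ValueError("pixels exceed the declared saturation level")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
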