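"""Baseline spot quantification methods: optical density and area-based volume.

Optical density (OD) quantifies a spot by the intensity of its single
most intense pixel; it ignores spot width entirely but is cheap and
fairly robust to overlap.

The area-based method sums pixel intensities over a region assigned to
each spot: all pixels above a fixed intensity threshold form the signal
region, its connected components are attributed to the peaks they
contain, and a component shared by two peaks P and Q is split by the
perpendicular to the inter-peak line through the minimum of the line
profile between them. When the profile has no interior valley — it
decreases monotonically from P to Q — the split degenerates to a line
through Q, the known failure mode of this scheme on strongly
overlapping spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage

from .detection import Peak
from .gaussian_fit import BackgroundModel
from .image import GelImage

__all__ = ["ODResult", "AreaSpot", "quantify_od", "quantify_area", "line_profile"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ODResult:
    """Optical density of one peak: the intensity of the peak pixel."""

    peak_id: int
    od: float


@dataclass(frozen=True)
class AreaSpot:
    """Thresholded-area quantification of one spot.

    ``pixel_rows`` / ``pixel_cols`` list the pixels assigned to the
    spot; ``volume`` is the sum of their intensities.
    """

    peak_id: int
    pixel_rows: np.ndarray
    pixel_cols: np.ndarray
    volume: float

    @property
    def n_pixels(self) -> int:
        return int(self.pixel_rows.size)


def quantify_od(
    image: GelImage,
    peaks: list[Peak],
    *,
    subtract_background: bool = False,
    mu_bg: BackgroundModel | None = None,
) -> list[ODResult]:
    """Peak-pixel intensity per spot, optionally above background."""
    if subtract_background and mu_bg is None:
        raise ValueError("subtract_background requires mu_bg")
    offset = mu_bg.mu_bg if subtract_background else 0.0
    out = []
    for i, p in enumerate(peaks):
        if not (0 <= p.y < image.height and 0 <= p.x < image.width):
            raise ValueError(f"peak {i} at ({p.x}, {p.y}) outside image bounds")
        out.append(ODResult(peak_id=i, od=float(image.pixels[p.y, p.x]) - offset))
    return out


def line_profile(image: GelImage, p: Peak, q: Peak) -> tuple[np.ndarray, np.ndarray]:
    """Intensity along the segment from p to q, sampled at about unit spacing.

    Returns (positions, intensities); positions are distances from p in
    pixels, the first sample sits exactly on p and the last on q.
    Values are bilinearly interpolated.
    """
    if p.x == q.x and p.y == q.y:
        raise ValueError("line profile endpoints coincide")
    dist = float(np.hypot(q.x - p.x, q.y - p.y))
    n = int(np.ceil(dist)) + 1
    frac = np.linspace(0.0, 1.0, n)
    rows = p.y + frac * (q.y - p.y)
    cols = p.x + frac * (q.x - p.x)
    vals = ndimage.map_coordinates(image.pixels, [rows, cols], order=1, mode="nearest")
    return frac * dist, vals


def _split_point(image: GelImage, p: Peak, q: Peak) -> np.ndarray:
    """Point on segment p-q through which the perpendicular split passes.

    The minimum of the line profile; a monotone profile puts it on an
    endpoint (the degenerate split through Q when Q is the dimmer spot).
    """
    positions, vals = line_profile(image, p, q)
    k = int(np.argmin(vals))
    frac = positions[k] / positions[-1]
    return np.array([p.y + frac * (q.y - p.y), p.x + frac * (q.x - p.x)])


def quantify_area(
    image: GelImage,
    peaks: list[Peak],
    threshold: float,
    *,
    subtract_background: bool = False,
    mu_bg: BackgroundModel | None = None,
) -> list[AreaSpot]:
    """Threshold-area volume per spot.

    Pixels strictly above ``threshold`` form the signal region;
    8-connected components are assigned to the peaks they contain
    (peakless components are dropped). A component holding several
    peaks is partitioned by perpendicular-bisector splits through the
    inter-peak profile minima, applied pairwise in order of increasing
    inter-peak distance. The volume is the raw intensity sum over the
    assigned pixels (optionally background-subtracted per pixel).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if subtract_background and mu_bg is None:
        raise ValueError("subtract_background requires mu_bg")
    offset = mu_bg.mu_bg if subtract_background else 0.0

    region = image.pixels > threshold
    labels, _ = ndimage.label(region, structure=np.ones((3, 3), dtype=int))

    empty = (np.array([], dtype=int), np.array([], dtype=int))
    assigned: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    by_component: dict[int, list[int]] = {}
    for i, p in enumerate(peaks):
        lab = int(labels[p.y, p.x])
        if lab == 0:
            logger.warning("peak %d at (%d, %d) lies below the area threshold", i, p.x, p.y)
            assigned[i] = empty
        else:
            by_component.setdefault(lab, []).append(i)

    for lab, member_ids in by_component.items():
        rows, cols = np.nonzero(labels == lab)
        if len(member_ids) == 1:
            assigned[member_ids[0]] = (rows, cols)
            continue
        pix = np.stack([rows, cols], axis=1).astype(float)
        eligible = np.ones((len(member_ids), len(rows)), dtype=bool)
        pairs = sorted(
            combinations(range(len(member_ids)), 2),
            key=lambda ij: np.hypot(
                peaks[member_ids[ij[0]]].x - peaks[member_ids[ij[1]]].x,
                peaks[member_ids[ij[0]]].y - peaks[member_ids[ij[1]]].y,
            ),
        )
        for a, b in pairs:
            pa, pb = peaks[member_ids[a]], peaks[member_ids[b]]
            m = _split_point(image, pa, pb)
            direction = np.array([pb.y - pa.y, pb.x - pa.x], dtype=float)
            side = (pix - m) @ direction  # <0: a's side, >0: b's side
            on_line = side == 0
            if on_line.any():
                da = np.hypot(pix[:, 0] - pa.y, pix[:, 1] - pa.x)
                db = np.hypot(pix[:, 0] - pb.y, pix[:, 1] - pb.x)
                side = np.where(on_line, np.where(da <= db, -1.0, 1.0), side)
            eligible[a] &= side < 0
            eligible[b] &= side > 0
        owner = np.full(len(rows), -1, dtype=int)
        for j in range(len(member_ids)):
            free = (owner == -1) & eligible[j]
            owner[free] = j
        if (owner == -1).any():
            # pixels cut away from every peak by the pairwise splits: nearest peak wins
            centers = np.array(
                [[peaks[i].y, peaks[i].x] for i in member_ids], dtype=float
            )
            dists = np.linalg.norm(pix[owner == -1, None, :] - centers[None, :, :], axis=2)
            owner[owner == -1] = np.argmin(dists, axis=1)
        for j, pid in enumerate(member_ids):
            sel = owner == j
            assigned[pid] = (rows[sel], cols[sel])

    out = []
    for i in range(len(peaks)):
        rows, cols = assigned[i]
        vol = float((image.pixels[rows, cols] - offset).sum()) if rows.size else 0.0
        out.append(AreaSpot(peak_id=i, pixel_rows=rows, pixel_cols=cols, volume=vol))
    return out
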