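"""Grouping of peaks into fitting compounds.

Spots closer than the compound edge length ``d`` influence each other's
pixels and must be fitted simultaneously. Peaks P and Q are *connected*
when ``|xP - xQ| <= d`` and ``|yP - yQ| <= d``; connectivity is extended
transitively (P connected to R via Q), so a compound is a connected
component of the peak adjacency graph. The component structure is
obtained by repeatedly squaring and re-binarizing the adjacency matrix
until a fixpoint — the reachability matrix — is reached.

Each compound's *compound area* is the union of axis-aligned squares of
edge ``d`` centered on its peaks, clipped to the image. The fusion rule
guarantees areas of distinct compounds never share a pixel, so each
compound can be fitted on its own pixels without cross-talk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import Peak

__all__ = [
    "CompoundParams",
    "Compound",
    "build_adjacency",
    "transitive_closure",
    "extract_compounds",
    "group_peaks",
]


@dataclass(frozen=True)
class CompoundParams:
    """``d``: edge length in pixels of the square compound area per spot.

    ``d`` should cover essentially the whole footprint of one spot; with
    spot widths sigma typically below the detection scale ``w``, the
    default used by the pipeline is ``d = 6 w`` (a +-3 sigma support
    holds more than 99 percent of a Gaussian spot's volume). A fitted
    sigma exceeding ``d / 6`` indicates ``d`` was chosen too small.
    """

    d: int

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1 pixel")


@dataclass(frozen=True)
class Compound:
    """A group of peaks fitted simultaneously.

    ``peak_ids`` indexes into the peak list the compound was built from;
    ``mask`` is a boolean raster of the compound area.
    """

    peak_ids: tuple[int, ...]
    mask: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of the compound area pixels."""
        return np.nonzero(self.mask)


def build_adjacency(peaks: list[Peak], d: int) -> np.ndarray:
    """First-order adjacency: 1 where both coordinate gaps are <= d (inclusive)."""
    if not peaks:
        raise ValueError("need at least one peak")
    if d < 1:
        raise ValueError("d must be >= 1")
    xs = np.array([p.x for p in peaks])
    ys = np.array([p.y for p in peaks])
    close_x = np.abs(xs[:, None] - xs[None, :]) <= d
    close_y = np.abs(ys[:, None] - ys[None, :]) <= d
    return (close_x & close_y).astype(np.uint8)


def transitive_closure(adj: np.ndarray) -> np.ndarray:
    """Reachability matrix by iterated squaring and re-binarization.

    Squaring doubles the path length represented by the matrix, so the
    fixpoint is reached in at most ceil(log2 N) + 1 iterations.
    """
    m = np.asarray(adj, dtype=bool)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.array_equal(m, m.T) or not m.diagonal().all():
        raise ValueError("adjacency matrix must be symmetric with unit diagonal")
    while True:
        squared = (m.astype(np.int64) @ m.astype(np.int64)) >= 1
        if np.array_equal(squared, m):
            return squared.astype(np.uint8)
        m = squared


def _square_mask(
    shape: tuple[int, int], peaks_xy: list[tuple[int, int]], d: int
) -> np.ndarray:
    """Union of edge-d squares centered at the given (x, y) peaks, clipped.

    For even ``d`` the square extends floor(d/2) pixels left/up and
    ``d - 1 - floor(d/2)`` right/down of the center (odd ``d`` is
    symmetric and recommended).
    """
    h, ww = shape
    lo = d // 2
    hi = d - 1 - lo
    mask = np.zeros(shape, dtype=bool)
    for x, y in peaks_xy:
        r0, r1 = max(0, y - lo), min(h, y + hi + 1)
        c0, c1 = max(0, x - lo), min(ww, x + hi + 1)
        mask[r0:r1, c0:c1] = True
    return mask


def extract_compounds(
    closure: np.ndarray,
    peaks: list[Peak],
    d: int,
    image_shape: tuple[int, int],
) -> list[Compound]:
    """Read compounds out of the reachability matrix and build their areas.

    One compound per distinct row pattern of the closure; compounds are
    ordered by their smallest peak index. Raises if two compound areas
    overlap, which would violate the fusion rule and signals an
    inconsistent closure.
    """
    closure = np.asarray(closure, dtype=bool)
    n = len(peaks)
    if closure.shape != (n, n):
        raise ValueError("closure size does not match the peak list")

    seen: set[int] = set()
    compounds: list[Compound] = []
    for i in range(n):
        if i in seen:
            continue
        members = tuple(int(j) for j in np.nonzero(closure[i])[0])
        seen.update(members)
        mask = _square_mask(image_shape, [(peaks[j].x, peaks[j].y) for j in members], d)
        compounds.append(Compound(peak_ids=members, mask=mask))

    if compounds:
        coverage = np.zeros(image_shape, dtype=np.int16)
        for c in compounds:
            coverage += c.mask
        if coverage.max() > 1:
            raise RuntimeError(
                "compound areas overlap; the closure is inconsistent with the fusion rule"
            )
    return compounds


def group_peaks(peaks: list[Peak], d: int, image_shape: tuple[int, int]) -> list[Compound]:
    """Convenience wrapper: adjacency -> closure -> compounds."""
    if not peaks:
        return []
    adj = build_adjacency(peaks, d)
    closure = transitive_closure(adj)
    return extract_compounds(closure, peaks, d, image_shape)
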