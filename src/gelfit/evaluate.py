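"""Quantification-quality metrics and truth matching.

alpha measures, in percent, how far a method's spot-pair signal ratio
deviates from the true simulated ratio:

    alpha = (signal_P / signal_Q) / (true_P / true_Q) - 1) * 100

The signed value is returned; aggregation across replicates uses |alpha|.
alpha_mean generalizes this to many spots as the mean absolute deviation
of the relative signal fractions from the true fractions (scale
invariant, like alpha).

For exposure series of the same blot, precision is summarized by the
coefficient of variation of each spot's *relative* signal (its fraction
of the total) across the series: a sound method gives near-constant
fractions no matter the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaussian_fit import SpotFit
from .simulate import SceneTruth

__all__ = [
    "AlphaResult",
    "SeriesCV",
    "MatchResult",
    "alpha",
    "alpha_mean",
    "relative_signals",
    "cv_across_series",
    "match_spots",
]


@dataclass(frozen=True)
class AlphaResult:
    """Signed percent deviation of a signal ratio from the true ratio."""

    alpha: float
    method: str = ""
    condition: str = ""


@dataclass(frozen=True)
class SeriesCV:
    """Per-spot CVs of relative signal across an image series, plus their mean."""

    per_spot: tuple[float, ...]
    mean: float


@dataclass(frozen=True)
class MatchResult:
    """Greedy one-to-one assignment of detections to ground-truth spots."""

    pairs: tuple[tuple[int, int], ...]  # (detection index, truth index)
    false_positives: tuple[int, ...]  # unmatched detection indices
    false_negatives: tuple[int, ...]  # unmatched truth indices

    @property
    def recall(self) -> float:
        n_truth = len(self.pairs) + len(self.false_negatives)
        return len(self.pairs) / n_truth if n_truth else float("nan")

    @property
    def precision(self) -> float:
        n_det = len(self.pairs) + len(self.false_positives)
        return len(self.pairs) / n_det if n_det else float("nan")


def alpha(signal_P: float, signal_Q: float, true_P: float, true_Q: float) -> float:
    """Percent deviation of signal_P/signal_Q from true_P/true_Q (signed)."""
    if signal_Q == 0 or true_Q == 0 or true_P == 0:
        raise ZeroDivisionError("alpha is undefined for zero reference signals")
    return ((signal_P / signal_Q) / (true_P / true_Q) - 1.0) * 100.0


def alpha_mean(signals: np.ndarray, truths: np.ndarray) -> float:
    """Multi-spot quantification error, percent.

    Mean over spots of |relative signal / relative truth - 1| * 100,
    where relative values are fractions of the respective totals. Zero
    when signals are proportional to truths at any positive scale.
    """
    signals = np.asarray(signals, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if signals.shape != truths.shape or signals.size < 2:
        raise ValueError("need matching signal/truth vectors of at least two spots")
    if np.any(truths <= 0):
        raise ValueError("all true signals must be positive")
    if signals.sum() == 0:
        raise ZeroDivisionError("total signal is zero; alpha_mean undefined")
    rel_s = signals / signals.sum()
    rel_t = truths / truths.sum()
    return float(np.mean(np.abs(rel_s / rel_t - 1.0)) * 100.0)


def relative_signals(signals: np.ndarray) -> np.ndarray:
    """Each spot's fraction of the total signal; fractions sum to 1."""
    signals = np.asarray(signals, dtype=float)
    if np.any(signals < 0):
        raise ValueError("signals must be non-negative")
    total = signals.sum()
    if total <= 0:
        raise ZeroDivisionError("total signal is zero")
    return signals / total


def cv_across_series(series: list[np.ndarray]) -> SeriesCV:
    """CV of each spot's relative signal across a series of images.

    ``series`` holds one relative-signal vector per image, with spot i
    at position i in every vector. Sample (n-1) SDs are used.
    """
    if len(series) < 2:
        raise ValueError("need at least two images in the series")
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2:
        raise ValueError("images in the series have mismatched spot counts")
    means = arr.mean(axis=0)
    if np.any(means == 0):
        raise ZeroDivisionError("a spot has zero mean relative signal")
    cvs = arr.std(axis=0, ddof=1) / means
    return SeriesCV(per_spot=tuple(float(c) for c in cvs), mean=float(cvs.mean()))


def match_spots(
    detected: list[SpotFit], truth: SceneTruth, radius: float
) -> MatchResult:
    """Greedy nearest-center one-to-one matching within ``radius`` pixels.

    Candidate pairs are taken in order of increasing center distance;
    detections and truths already claimed are skipped. Leftover
    detections are false positives, leftover truths false negatives.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    det_xy = np.array([[f.x0, f.y0] for f in detected], dtype=float).reshape(-1, 2)
    tru_xy = np.array(
        [[s.x0, s.y0] for s in truth.spec.spots], dtype=float
    ).reshape(-1, 2)

    if det_xy.size and tru_xy.size:
        dists = np.linalg.norm(det_xy[:, None, :] - tru_xy[None, :, :], axis=2)
        order = np.argsort(dists, axis=None)
    else:
        dists = np.zeros((len(detected), len(truth.spec.spots)))
        order = np.array([], dtype=int)

    used_det: set[int] = set()
    used_tru: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = np.unravel_index(flat, dists.shape)
        if dists[i, j] > radius:
            break
        if i in used_det or j in used_tru:
            continue
        pairs.append((int(i), int(j)))
        used_det.add(int(i))
        used_tru.add(int(j))

    fps = tuple(i for i in range(len(detected)) if i not in used_det)
    fns = tuple(j for j in range(len(truth.spec.spots)) if j not in used_tru)
    return MatchResult(pairs=tuple(pairs), false_positives=fps, false_negatives=fns)
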