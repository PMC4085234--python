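import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gelfit.detection import Peak

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_peak(x: int, y: int, original: float = 0.0, restored: float = 0.0) -> Peak:
    return Peak(x=x, y=y, restored_intensity=restored, original_intensity=original)


def seed_peaks_from_truth(image, truth) -> list[Peak]:
    """Peak list at the rounded true spot centers (seed-list input)."""
    peaks = []
    for s in truth.spec.spots:
        x, y = int(round(s.x0)), int(round(s.y0))
        peaks.append(
            Peak(x=x, y=y, restored_intensity=0.0, original_intensity=float(image.pixels[y, x]))
        )
    return peaks


def render_gaussian(shape, x0, y0, amplitude, sigma, background=0.0):
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return background + amplitude * np.exp(
        -0.5 * ((xs - x0) ** 2 + (ys - y0) ** 2) / sigma**2
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
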