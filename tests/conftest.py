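import numpy as np
import pytest

from detrunc.geometry import DetectorGeometry
from detrunc.histogram import PixelHistogram
from detrunc.image_io import ImageFrame
from detrunc.lognormal_model import LognormalParams


def make_histogram(
    values: np.ndarray, i_max: int, annulus: int = 0
) -> PixelHistogram:
    """Build a PixelHistogram directly from a 1-D array of observed values."""
    values = np.asarray(values, dtype=np.int64)
    assert values.size == 0 or values.min() >= 0
    in_range = values[values <= i_max]
    counts = np.bincount(in_range, minlength=i_max + 1).astype(np.int64)
    n_zero = int(counts[0])
    return PixelHistogram(
        counts=counts,
        i_max=int(i_max),
        n_total=int(values.size),
        n_overflow=int(values.size - in_range.size),
        annulus=annulus,
        zero_locations=np.zeros((n_zero, 2), dtype=np.int64),
    )


def sample_truncated(
    p: LognormalParams, n: int, seed: int, i_max_quantile: float = 0.99
) -> PixelHistogram:
    """Draw n rounded shifted-lognormal values, clamp at zero, histogram them."""
    rng = np.random.default_rng(seed)
    draws = p.tau + rng.lognormal(p.mu, p.sigma, n)
    observed = np.maximum(np.rint(draws).astype(np.int64), 0)
    i_max = int(np.quantile(observed, i_max_quantile))
    return make_histogram(observed, i_max)


def square_geometry(n_pixels: int = 64, n_annuli_hint: int = 4) -> DetectorGeometry:
    """A centered square detector with study-condition optics, scaled down."""
    scale = 4096 / n_pixels
    return DetectorGeometry.from_voltage(
        voltage_kv=200.0,
        distance=2200.0,
        beam_center=((n_pixels - 1) / 2.0, (n_pixels - 1) / 2.0),
        pixel_size=0.0156 * scale,
        n_fast=n_pixels,
        n_slow=n_pixels,
    )


def frame_from_array(values: np.ndarray, signed: bool = False) -> ImageFrame:
    return ImageFrame(pixels=np.asarray(values), signed=signed)


@pytest.fixture
def reference_params() -> LognormalParams:
    """A shifted lognormal with appreciable mass below zero."""
    return LognormalParams(mu=5.0, sigma=0.5, tau=-100.0)
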