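"""Synthetic truncated diffraction frames with known ground truth.

The generator emulates the pathology the corrector addresses: a
radially varying background whose per-annulus distribution is a shifted
lognormal with mode and variance decreasing toward high resolution,
optional Gaussian Bragg spots, and hard clamping of negative counts to
zero as produced by dark-frame subtraction and gain correction stored
in unsigned 16-bit integers.  Background counts are drawn i.i.d. per
pixel within an annulus — the model's own assumption — so the
simulation tests the method under its stated conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DetectorGeometry, equal_area_annuli
from .image_io import U16_MAX, ImageFrame
from .lognormal_model import LognormalParams


@dataclass(frozen=True)
class GaussianSpot:
    """An isotropic Gaussian Bragg spot added before truncation."""

    center: tuple[float, float]  # (fast, slow) pixels
    intensity: float  # integrated counts (ADU)
    width: float  # standard deviation (pixels)


@dataclass
class SimulationSpec:
    """Ground-truth description of one simulated frame.

    ``params[k]`` gives the shifted-lognormal background of annulus k;
    modes must decrease outward (higher resolution, lower background).
    """

    geometry: DetectorGeometry
    params: list[LognormalParams]
    spots: list[GaussianSpot] = field(default_factory=list)
    beam_stop_radius: float = 0.0  # mm; pixels inside are masked invalid
    seed: int = 0

    @property
    def n_annuli(self) -> int:
        return len(self.params)

    def __post_init__(self) -> None:
        if not self.params:
            raise ValueError("at least one annulus parameter triple required")
        modes = [p.mode for p in self.params]
        if any(b >= a for a, b in zip(modes, modes[1:])):
            raise ValueError(
                f"per-annulus modes must decrease outward, got {modes}"
            )


def graded_params(
    n_annuli: int = 10,
    mode_inner: float = 600.0,
    mode_outer: float = 50.0,
    sigma_inner: float = 0.55,
    sigma_outer: float = 0.35,
    tau_inner: float = -140.0,
    tau_outer: float = -45.0,
) -> list[LognormalParams]:
    """Default per-annulus parameters emulating a MicroED background.

    The mode decays geometrically from ``mode_inner`` to ``mode_outer``
    ADU and σ and τ interpolate linearly, so both the mode and the
    variance of the background decrease toward high resolution.  The
    outer annuli put appreciable mass below zero and therefore suffer
    truncation.
    """
    out = []
    for k in range(n_annuli):
        t = k / max(n_annuli - 1, 1)
        mode = mode_inner * (mode_outer / mode_inner) ** t
        sigma = sigma_inner + (sigma_outer - sigma_inner) * t
        tau = tau_inner + (tau_outer - tau_inner) * t
        mu = np.log(mode - tau) + sigma**2
        out.append(LognormalParams(mu=float(mu), sigma=float(sigma), tau=float(tau)))
    return out


def default_spec(
    n_pixels: int = 256,
    n_annuli: int = 10,
    seed: int = 0,
    spots: list[GaussianSpot] | None = None,
) -> SimulationSpec:
    """A study-condition frame: 200 kV, 2.2 m virtual distance camera.

    The pixel grid is scaled down from the physical 4096² detector while
    keeping its angular extent, so the same resolution range is covered.
    """
    scale = 4096 / n_pixels
    geom = DetectorGeometry.from_voltage(
        voltage_kv=200.0,
        distance=2200.0,
        beam_center=((n_pixels - 1) / 2.0, (n_pixels - 1) / 2.0),
        pixel_size=0.0156 * scale,
        n_fast=n_pixels,
        n_slow=n_pixels,
    )
    return SimulationSpec(
        geometry=geom,
        params=graded_params(n_annuli),
        spots=spots or [],
        seed=seed,
    )


def _spot_contribution(spec: SimulationSpec) -> np.ndarray:
    geom = spec.geometry
    total = np.zeros((geom.n_slow, geom.n_fast))
    fast = np.arange(geom.n_fast)
    slow = np.arange(geom.n_slow)
    for spot in spec.spots:
        df = fast - spot.center[0]
        ds = slow - spot.center[1]
        g = np.exp(
            -(df[np.newaxis, :] ** 2 + ds[:, np.newaxis] ** 2) / (2 * spot.width**2)
        )
        total += spot.intensity * g / (2 * np.pi * spot.width**2)
    return total


def simulate_frame(spec: SimulationSpec) -> tuple[ImageFrame, ImageFrame]:
    """Draw a (truth, observed) frame pair from ``spec``.

    The truth frame holds the signed integer counts before storage; the
    observed frame is the truth with negative values clamped to zero,
    as unsigned storage would record it.  Deterministic given the seed.
    """
    geom = spec.geometry
    mask = np.ones((geom.n_slow, geom.n_fast), dtype=bool)
    if spec.beam_stop_radius > 0:
        from .geometry import radius_map

        mask &= radius_map(geom) >= spec.beam_stop_radius
    partition = equal_area_annuli(geom, spec.n_annuli, mask)
    rng = np.random.default_rng(spec.seed)
    values = np.zeros((geom.n_slow, geom.n_fast), dtype=float)
    for k, p in enumerate(spec.params):
        sel = partition.annulus_index == k
        n = int(sel.sum())
        draws = p.tau + rng.lognormal(mean=p.mu, sigma=p.sigma, size=n)
        values[sel] = draws
    values += _spot_contribution(spec)
    truth_pixels = np.rint(values).astype(np.int32)
    truth_pixels[~mask] = 0
    truth_pixels = np.minimum(truth_pixels, U16_MAX)

    header = {
        "HEADER_BYTES": "512",
        "DIM": "2",
        "TYPE": "unsigned_short",
        "BYTE_ORDER": "little_endian",
        "SIZE1": str(geom.n_fast),
        "SIZE2": str(geom.n_slow),
        **geom.header_entries(),
    }
    truth = ImageFrame(
        pixels=truth_pixels, header=dict(header), valid_mask=mask, signed=True
    )
    observed = truncate(truth)
    return truth, observed


def truncate(frame: ImageFrame) -> ImageFrame:
    """Clamp negative counts to zero, as unsigned storage does."""
    out = frame.copy()
    out.pixels = np.maximum(out.pixels, 0)
    out.signed = False
    return out
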