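"""Detector geometry: pixel → resolution mapping and equal-area annuli.

The scattering geometry is the flat-detector small-angle setup of a
transmission electron microscope operated in diffraction mode: a pixel
at physical radius ``r`` from the beam center, with the detector at a
virtual distance ``D``, records scattering angle ``2θ = atan(r / D)``
and hence a lattice d-spacing ``d = λ / (2 sin θ)`` by Bragg's law.
The electron wavelength follows from the acceleration voltage via the
relativistic de Broglie relation.

Resolution shells are realized as concentric annuli holding
approximately equal numbers of valid pixels, constructed from quantiles
of the per-pixel radius distribution.  This keeps shells balanced on a
square detector (whose corners extend beyond the inscribed circle) and
under arbitrary masks, without special cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .exceptions import DegeneratePartitionError
from .image_io import ImageFrame


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å at ``voltage_kv`` kilovolts.

    λ = h / sqrt(2 m₀ e V (1 + e V / (2 m₀ c²))), CODATA constants.
    """
    if voltage_kv <= 0:
        raise ValueError(f"acceleration voltage must be positive, got {voltage_kv}")
    v = voltage_kv * 1e3
    ev = constants.e * v
    lam_m = constants.h / np.sqrt(
        2.0 * constants.m_e * ev * (1.0 + ev / (2.0 * constants.m_e * constants.c**2))
    )
    return lam_m * 1e10


@dataclass(frozen=True)
class DetectorGeometry:
    """Diffraction geometry of one detector.

    Attributes
    ----------
    wavelength
        Electron wavelength in Å.
    distance
        Virtual detector distance in mm.
    beam_center
        ``(fast, slow)`` beam-center position in pixels, 0-based with
        pixel centers at integer coordinates.
    pixel_size
        Pixel edge length in mm.
    n_fast, n_slow
        Pixel grid dimensions.
    """

    wavelength: float
    distance: float
    beam_center: tuple[float, float]
    pixel_size: float
    n_fast: int
    n_slow: int

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        cf, cs = self.beam_center
        if not (0 <= cf < self.n_fast and 0 <= cs < self.n_slow):
            warnings.warn(
                f"beam center {self.beam_center} lies outside the "
                f"{self.n_fast}×{self.n_slow} pixel grid",
                stacklevel=2,
            )

    @classmethod
    def from_voltage(
        cls,
        voltage_kv: float,
        distance: float,
        beam_center: tuple[float, float],
        pixel_size: float,
        n_fast: int,
        n_slow: int,
    ) -> "DetectorGeometry":
        """Build a geometry from the acceleration voltage in kV."""
        return cls(
            wavelength=electron_wavelength(voltage_kv),
            distance=distance,
            beam_center=beam_center,
            pixel_size=pixel_size,
            n_fast=n_fast,
            n_slow=n_slow,
        )

    @classmethod
    def from_frame(cls, frame: ImageFrame, **overrides) -> "DetectorGeometry":
        """Read geometry from SMV header keys; ``overrides`` win.

        Header beam centers (BEAM_CENTER_X/Y) are in millimeters and
        converted to pixels via PIXEL_SIZE; X maps to the fast axis.
        """
        h = frame.header
        pixel_size = overrides.get("pixel_size", float(h["PIXEL_SIZE"]))
        if "beam_center" in overrides:
            beam_center = overrides["beam_center"]
        else:
            beam_center = (
                float(h["BEAM_CENTER_X"]) / pixel_size,
                float(h["BEAM_CENTER_Y"]) / pixel_size,
            )
        return cls(
            wavelength=overrides.get("wavelength", float(h["WAVELENGTH"])),
            distance=overrides.get("distance", float(h["DISTANCE"])),
            beam_center=beam_center,
            pixel_size=pixel_size,
            n_fast=frame.n_fast,
            n_slow=frame.n_slow,
        )

    def header_entries(self) -> dict[str, str]:
        """Geometry as SMV header key/value strings (beam center in mm)."""
        cf, cs = self.beam_center
        return {
            "PIXEL_SIZE": f"{self.pixel_size:.6f}",
            "DISTANCE": f"{self.distance:.4f}",
            "WAVELENGTH": f"{self.wavelength:.8f}",
            "BEAM_CENTER_X": f"{cf * self.pixel_size:.6f}",
            "BEAM_CENTER_Y": f"{cs * self.pixel_size:.6f}",
        }


def radius_map(geom: DetectorGeometry) -> np.ndarray:
    """Physical radius (mm) of every pixel center from the beam center."""
    cf, cs = geom.beam_center
    fast = np.arange(geom.n_fast) - cf
    slow = np.arange(geom.n_slow) - cs
    return geom.pixel_size * np.hypot(fast[np.newaxis, :], slow[:, np.newaxis])


def radius_to_resolution(geom: DetectorGeometry, r_mm) -> np.ndarray:
    """d-spacing (Å) at physical radius ``r_mm``; +inf at the beam center."""
    r = np.asarray(r_mm, dtype=float)
    two_theta = np.arctan2(r, geom.distance)
    with np.errstate(divide="ignore"):
        d = geom.wavelength / (2.0 * np.sin(0.5 * two_theta))
    return d


def pixel_resolution(geom: DetectorGeometry, pixel: tuple[float, float]) -> float:
    """d-spacing (Å) of one ``(fast, slow)`` pixel; +inf at the beam center."""
    cf, cs = geom.beam_center
    r = geom.pixel_size * float(np.hypot(pixel[0] - cf, pixel[1] - cs))
    return float(radius_to_resolution(geom, r))


def resolution_map(geom: DetectorGeometry) -> np.ndarray:
    """Per-pixel d-spacing map in Å."""
    return radius_to_resolution(geom, radius_map(geom))


@dataclass(frozen=True)
class AnnulusPartition:
    """Partition of the detector into concentric resolution shells.

    ``boundaries`` holds ``n + 1`` ascending radii in mm (first 0, last
    at least the maximum valid-pixel radius); ``annulus_index`` labels
    each pixel with its shell in ``[0, n)``, or −1 for invalid pixels.
    """

    boundaries: np.ndarray
    annulus_index: np.ndarray

    @property
    def n_annuli(self) -> int:
        return len(self.boundaries) - 1

    def pixel_counts(self) -> np.ndarray:
        """Number of valid pixels in each annulus."""
        valid = self.annulus_index >= 0
        return np.bincount(
            self.annulus_index[valid], minlength=self.n_annuli
        )


def equal_area_annuli(
    geom: DetectorGeometry, n: int, mask: np.ndarray | None = None
) -> AnnulusPartition:
    """Split the detector into ``n`` annuli of near-equal valid-pixel count.

    Boundaries are the ``k/n`` quantiles of the valid-pixel radius
    distribution; each valid pixel is labelled with the half-open
    interval ``[r_k, r_{k+1})`` containing its radius (last interval
    closed).  Raises :class:`DegeneratePartitionError` when there are
    fewer distinct radii than annuli.
    """
    if n < 1:
        raise ValueError(f"need at least one annulus, got n={n}")
    radii = radius_map(geom)
    if mask is None:
        mask = np.ones(radii.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    valid_r = radii[mask]
    if valid_r.size < n:
        raise DegeneratePartitionError(
            f"only {valid_r.size} valid pixels for {n} annuli"
        )
    inner = np.quantile(valid_r, np.arange(1, n) / n)
    boundaries = np.concatenate(([0.0], inner, [valid_r.max()]))
    if np.any(np.diff(boundaries) <= 0):
        raise DegeneratePartitionError(
            f"radius quantiles are not strictly increasing for n={n}; "
            "too few distinct radii"
        )
    index = np.searchsorted(inner, radii, side="right").astype(np.int32)
    index[~mask] = -1
    return AnnulusPartition(boundaries=boundaries, annulus_index=index)
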