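"""Restore clamped negative counts in truncated diffraction frames.

Per annulus, the fitted shifted lognormal prescribes the frequencies of
the true counts I ≤ 0 hiding behind the observed zeros.  The expected
frequencies are integerized deterministically (largest-remainder
rounding, so they sum exactly to N₀) and only the spatial arrangement
of the values over the zero-valued pixels is random, drawn from a
seeded generator.  Pixels with positive values are never touched, and a
frame without zeros passes through bitwise unchanged.

Because corrected frames may hold negative counts, a sweep-wide storage
offset — the negated minimum corrected count over all frames — is
applied at write time and recorded as ADCOFFSET.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    EmptyAnnulusError,
    FitError,
    InsufficientDataError,
    ModelInconsistencyError,
)
from .geometry import DetectorGeometry, equal_area_annuli
from .histogram import PixelHistogram, build_histogram
from .image_io import ImageFrame
from .lognormal_model import LognormalParams, prob_nonpositive
from .ml_fit import FitResult, fit_annulus

# extend the assigned-value range down to where the expected number of
# pixels in the remaining left tail drops below half a pixel
_TAIL_CUTOFF = 0.5


@dataclass
class AnnulusCorrection:
    """What happened in one annulus of one frame."""

    annulus: int
    n_zero: int
    fit: FitResult | None
    assigned: dict[int, int]  # value (≤ 0) → count

    def __post_init__(self) -> None:
        assert all(v <= 0 for v in self.assigned)
        if self.fit is not None:
            assert sum(self.assigned.values()) == self.n_zero


@dataclass
class CorrectionReport:
    """Everything needed to reproduce one frame's correction."""

    frame_id: str
    seed: int
    annuli: list[AnnulusCorrection] = field(default_factory=list)
    offset: int | None = None  # sweep-wide, filled at write time

    def total_assigned(self) -> int:
        return sum(sum(a.assigned.values()) for a in self.annuli)

    def to_dict(self) -> dict:
        return {
            "frame_id": self.frame_id,
            "seed": self.seed,
            "offset": self.offset,
            "annuli": [
                {
                    "annulus": a.annulus,
                    "n_zero": a.n_zero,
                    "fit": None
                    if a.fit is None
                    else {
                        "mu": a.fit.params.mu,
                        "sigma": a.fit.params.sigma,
                        "tau": a.fit.params.tau,
                        "loglik": a.fit.loglik,
                        "rmsd": a.fit.rmsd,
                        "converged": a.fit.converged,
                    },
                    "assigned": {str(k): v for k, v in sorted(a.assigned.items())},
                }
                for a in self.annuli
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def negative_value_counts(n_zero: int, p: LognormalParams) -> dict[int, int]:
    """Integer frequencies of the true counts behind ``n_zero`` zeros.

    Expected counts e_I = n_zero · P(I) / F(½) for I = 0, −1, −2, …,
    truncated where the remaining left tail holds fewer than half an
    expected pixel, then integerized by largest-remainder rounding so
    the total is exactly ``n_zero``.  Deterministic.  A value of 0 may
    be assigned: an observed zero can be a true zero.
    """
    if n_zero < 0:
        raise ValueError("n_zero must be nonnegative")
    if n_zero == 0:
        return {}
    f_half = prob_nonpositive(p)
    if f_half <= 0.0:
        raise ModelInconsistencyError(
            f"{n_zero} zero pixels but the fitted model has no mass below +1/2"
        )
    dist = p.frozen()
    # include I while the cumulative expected count up to I stays >= cutoff
    values = []
    expected = []
    i = 0
    while True:
        cum = n_zero * dist.cdf(i + 0.5) / f_half
        if cum < _TAIL_CUTOFF and i < 0:
            break
        values.append(i)
        expected.append(n_zero * (dist.cdf(i + 0.5) - dist.cdf(i - 0.5)) / f_half)
        if i - 0.5 <= p.tau:
            break
        i -= 1
    expected = np.asarray(expected)
    # fold the discarded tail back so the expectations sum to n_zero
    expected *= n_zero / expected.sum()
    floors = np.floor(expected).astype(np.int64)
    remainder = int(n_zero - floors.sum())
    # stable order: larger fractional part first, ties to larger value
    frac = expected - floors
    order = np.argsort(-frac, kind="stable")
    counts = floors.copy()
    counts[order[:remainder]] += 1
    return {int(v): int(c) for v, c in zip(values, counts) if c > 0}


def assign_negatives(
    frame: ImageFrame,
    zero_locations: np.ndarray,
    counts: dict[int, int],
    seed,
) -> ImageFrame:
    """Place the values of ``counts`` on ``zero_locations`` at random.

    The multiset of values placed equals ``counts`` exactly; only the
    permutation mapping values to pixels is drawn from the seeded
    generator.  Every other pixel is bitwise unchanged; the returned
    frame is flagged signed.
    """
    zero_locations = np.asarray(zero_locations).reshape(-1, 2)
    total = sum(counts.values())
    if total != len(zero_locations):
        raise ValueError(
            f"{len(zero_locations)} zero pixels but {total} assigned values"
        )
    rows, cols = zero_locations[:, 0], zero_locations[:, 1]
    current = frame.pixels[rows, cols]
    if np.any(current != 0) or not np.all(frame.valid_mask[rows, cols]):
        raise ValueError("assignment targets must be valid zero-valued pixels")
    out = frame.copy()
    out.pixels = out.pixels.astype(np.int32)
    out.signed = True
    if total == 0:
        return out
    values = np.concatenate(
        [np.full(c, v, dtype=np.int32) for v, c in sorted(counts.items(), reverse=True)]
    )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(total)
    out.pixels[rows, cols] = values[perm]
    return out


def correct_frame(
    frame: ImageFrame,
    geom: DetectorGeometry,
    n_annuli: int = 10,
    seed: int = 0,
    i_max: int | None = None,
    on_nonconverged: str = "fail",
    frame_id: str = "",
) -> tuple[ImageFrame, CorrectionReport]:
    """Apply the truncation correction to one unsigned frame.

    Per annulus: build the censored histogram, fit the shifted
    lognormal by maximum likelihood, integerize the implied negative
    frequencies, and scatter them over the zero-valued pixels with a
    per-annulus random stream derived from ``seed``.  Annuli without
    zeros are untouched; a frame without zeros is returned bitwise
    identical (apart from the signed flag).

    ``on_nonconverged`` is ``"fail"`` (raise :class:`FitError`) or
    ``"skip"`` (leave the annulus uncorrected, with a warning).
    """
    if frame.signed:
        raise ValueError("correct_frame expects an unsigned, pre-correction frame")
    if on_nonconverged not in ("fail", "skip"):
        raise ValueError("on_nonconverged must be 'fail' or 'skip'")
    partition = equal_area_annuli(geom, n_annuli, frame.valid_mask)
    report = CorrectionReport(frame_id=frame_id, seed=int(seed))
    out = frame.copy()
    out.pixels = out.pixels.astype(np.int32)
    out.signed = True
    for k in range(n_annuli):
        try:
            h = build_histogram(frame, partition, k, i_max=i_max)
        except EmptyAnnulusError:
            if on_nonconverged == "fail":
                raise
            warnings.warn(f"annulus {k}: empty after masking, skipped", stacklevel=2)
            continue
        if h.n_zero == 0:
            report.annuli.append(AnnulusCorrection(k, 0, None, {}))
            continue
        try:
            fit = fit_annulus(h)
        except InsufficientDataError as exc:
            if on_nonconverged == "fail":
                raise FitError(str(exc)) from exc
            warnings.warn(f"annulus {k}: {exc}; left uncorrected", stacklevel=2)
            report.annuli.append(AnnulusCorrection(k, h.n_zero, None, {}))
            continue
        if not fit.converged:
            msg = f"annulus {k}: fit did not converge in {fit.n_iter} iterations"
            if on_nonconverged == "fail":
                raise FitError(msg)
            warnings.warn(msg + "; left uncorrected", stacklevel=2)
            report.annuli.append(AnnulusCorrection(k, h.n_zero, None, {}))
            continue
        counts = negative_value_counts(h.n_zero, fit.params)
        out = assign_negatives(out, h.zero_locations, counts, seed=[int(seed), k])
        report.annuli.append(AnnulusCorrection(k, h.n_zero, fit, counts))
    return out, report


def compute_offset(frames) -> int:
    """Sweep-wide storage offset: −min valid corrected count, clamped ≥ 0."""
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    lo = min(int(f.pixels[f.valid_mask].min()) for f in frames)
    return max(0, -lo)
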