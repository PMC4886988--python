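"""Per-annulus integer histograms with a censored zero bin.

The fit operates on the histogram N_I of pixel values I within one
resolution annulus.  Observed zeros are ambiguous — a zero may be a
true zero count or a negative count clamped by unsigned storage — so
the zero bin N₀ is tracked separately, together with the coordinates of
the zero-valued pixels so that imputed values can later be placed.
Saturated pixels (65535 ADU) carry the clamping pathology at the
opposite extreme and are excluded from modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyAnnulusError
from .geometry import AnnulusPartition
from .image_io import U16_MAX, ImageFrame

#: Default cap on the fit-range upper bound, in ADU.  The model targets
#: the low-valued background pixels; Bragg-peak tails must not dominate
#: the likelihood.
I_MAX_CAP = 2000

#: Default quantile of positive valid pixel values used for the
#: fit-range upper bound.
I_MAX_QUANTILE = 0.95


@dataclass
class PixelHistogram:
    """Histogram of valid pixel values in one annulus.

    ``counts[I]`` is N_I for ``I`` in ``[0, i_max]``; pixels above
    ``i_max`` are counted in ``n_overflow`` and excluded from the fit
    range.  ``zero_locations`` is an ``(N₀, 2)`` array of ``(slow,
    fast)`` indices of the zero-valued pixels.
    """

    counts: np.ndarray
    i_max: int
    n_total: int
    n_overflow: int
    annulus: int
    zero_locations: np.ndarray

    @property
    def n_zero(self) -> int:
        return int(self.counts[0])

    def __post_init__(self) -> None:
        assert len(self.counts) == self.i_max + 1
        assert int(self.counts.sum()) + self.n_overflow == self.n_total
        assert len(self.zero_locations) == self.counts[0]

    def values(self) -> np.ndarray:
        """Bin values ``0 … i_max`` (convenience for plotting/fitting)."""
        return np.arange(self.i_max + 1)

    def to_tsv(self, path) -> None:
        """Dump the histogram as tab-separated ``(I, N_I)`` text."""
        with open(path, "w") as fh:
            fh.write("I\tN_I\n")
            for i, n in enumerate(self.counts):
                fh.write(f"{i}\t{int(n)}\n")


def default_i_max(values: np.ndarray) -> int:
    """Fit-range upper bound: 95th percentile of positive values, capped.

    ``values`` are the valid pixel values of one annulus.
    """
    positive = values[values > 0]
    if positive.size == 0:
        return 1
    return int(min(np.quantile(positive, I_MAX_QUANTILE), I_MAX_CAP))


def build_histogram(
    frame: ImageFrame,
    partition: AnnulusPartition,
    annulus: int,
    i_max: int | None = None,
) -> PixelHistogram:
    """Histogram the valid pixels of ``annulus`` in an unsigned frame.

    Masked pixels and saturated pixels contribute nothing.  Raises
    :class:`EmptyAnnulusError` if no valid pixel remains.
    """
    if frame.signed:
        raise ValueError("histograms are built from unsigned, pre-correction frames")
    if not 0 <= annulus < partition.n_annuli:
        raise ValueError(f"annulus {annulus} outside [0, {partition.n_annuli})")
    sel = (partition.annulus_index == annulus) & frame.valid_mask
    sel &= frame.pixels != U16_MAX
    values = frame.pixels[sel]
    if values.size == 0:
        raise EmptyAnnulusError(f"annulus {annulus} has no valid pixels")
    if i_max is None:
        i_max = default_i_max(values)
    in_range = values[values <= i_max]
    counts = np.bincount(in_range, minlength=i_max + 1).astype(np.int64)
    zero_locations = np.argwhere(sel & (frame.pixels == 0))
    return PixelHistogram(
        counts=counts,
        i_max=int(i_max),
        n_total=int(values.size),
        n_overflow=int(values.size - in_range.size),
        annulus=annulus,
        zero_locations=zero_locations,
    )
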