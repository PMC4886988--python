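"""Reading and writing SMV-dialect detector images.

The SMV container used here is the ADSC convention consumed by most
crystallographic integration software: a fixed-size ASCII header of
``KEY=value;`` lines framed by ``{``/``}`` and zero-padded to
``HEADER_BYTES`` (512 by default), followed by a row-major unsigned
16-bit pixel payload.  Corrected images may contain negative counts;
those are stored by adding a constant offset, recorded under the
``ADCOFFSET`` header key so that downstream software can subtract it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .exceptions import PixelRangeError, SMVFormatError, TruncatedFileError

HEADER_BYTES = 512

_REQUIRED_KEYS = ("HEADER_BYTES", "SIZE1", "SIZE2", "TYPE", "BYTE_ORDER")

U16_MAX = 65535


@dataclass
class ImageFrame:
    """A detector frame: pixel counts, header metadata and validity mask.

    Parameters
    ----------
    pixels
        2-D integer array of counts in ADU, shape ``(slow, fast)`` =
        ``(SIZE2, SIZE1)``.
    header
        Key → string map of SMV header entries, preserved verbatim on
        read and pass-through on write.
    valid_mask
        Boolean array of the same shape; ``True`` marks pixels that
        participate in modeling (e.g. not shadowed by the beam stop).
    signed
        ``False`` while the frame is known to hold raw unsigned counts;
        set to ``True`` once a correction may have introduced negative
        values.
    """

    pixels: np.ndarray
    header: dict[str, str] = field(default_factory=dict)
    valid_mask: np.ndarray | None = None
    signed: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.pixels.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.pixels.shape:
            raise ValueError("valid_mask shape must match pixels")
        if not self.signed and self.pixels.size:
            lo, hi = self.pixels.min(), self.pixels.max()
            if lo < 0 or hi > U16_MAX:
                raise ValueError(
                    f"unsigned frame has out-of-range value(s) [{lo}, {hi}]"
                )

    @property
    def n_fast(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_slow(self) -> int:
        return self.pixels.shape[0]

    def copy(self) -> "ImageFrame":
        return ImageFrame(
            pixels=self.pixels.copy(),
            header=dict(self.header),
            valid_mask=self.valid_mask.copy(),
            signed=self.signed,
        )


def _parse_header(raw: bytes) -> dict[str, str]:
    text = raw.decode("ascii", errors="replace")
    header: dict[str, str] = {}
    body = text
    if "{" in body:
        body = body.split("{", 1)[1]
    if "}" in body:
        body = body.split("}", 1)[0]
    for line in body.splitlines():
        line = line.strip().rstrip(";")
        if not line or "=" not in line:
            continue
        key, value = line.split("=", 1)
        header[key.strip()] = value.strip()
    return header


def read_smv(path: str | os.PathLike) -> ImageFrame:
    """Read an SMV image into an :class:`ImageFrame`.

    All header keys are preserved verbatim; the validity mask is
    initialized all-true.  Raises :class:`SMVFormatError` when a
    required key is missing and :class:`TruncatedFileError` when the
    payload is shorter than ``SIZE1 × SIZE2 × 2`` bytes.
    """
    with open(path, "rb") as fh:
        head = fh.read(HEADER_BYTES)
        header = _parse_header(head)
        if "HEADER_BYTES" not in header:
            raise SMVFormatError(f"{path}: header missing key HEADER_BYTES")
        declared = int(header["HEADER_BYTES"])
        if declared > HEADER_BYTES:
            head += fh.read(declared - HEADER_BYTES)
            header = _parse_header(head)
        for key in _REQUIRED_KEYS:
            if key not in header:
                raise SMVFormatError(f"{path}: header missing key {key}")
        if header["TYPE"] != "unsigned_short":
            raise SMVFormatError(
                f"{path}: unsupported TYPE={header['TYPE']!r}"
            )
        n_fast = int(header["SIZE1"])
        n_slow = int(header["SIZE2"])
        order = header["BYTE_ORDER"]
        if order == "little_endian":
            dtype = np.dtype("<u2")
        elif order == "big_endian":
            dtype = np.dtype(">u2")
        else:
            raise SMVFormatError(f"{path}: unsupported BYTE_ORDER={order!r}")
        payload = fh.read(n_fast * n_slow * 2)
    if len(payload) < n_fast * n_slow * 2:
        raise TruncatedFileError(
            f"{path}: payload holds {len(payload)} bytes, "
            f"expected {n_fast * n_slow * 2}"
        )
    pixels = (
        np.frombuffer(payload, dtype=dtype)
        .reshape(n_slow, n_fast)
        .astype(np.int32)
    )
    return ImageFrame(pixels=pixels, header=header)


def write_smv(
    frame: ImageFrame,
    path: str | os.PathLike,
    offset: int = 0,
    byte_order: str = "little_endian",
) -> None:
    """Write ``frame`` as an SMV image, storing ``pixel + offset``.

    The offset is recorded in the header under ``ADCOFFSET``.  Every
    shifted value must lie in the unsigned 16-bit range, otherwise a
    :class:`PixelRangeError` reports the offending extremum.
    """
    pixels = np.asarray(frame.pixels, dtype=np.int64)
    lo = int(pixels.min()) if pixels.size else 0
    hi = int(pixels.max()) if pixels.size else 0
    if lo + offset < 0:
        raise PixelRangeError(
            f"minimum pixel {lo} with offset {offset} stores below 0"
        )
    if hi + offset > U16_MAX:
        raise PixelRangeError(
            f"maximum pixel {hi} with offset {offset} stores above {U16_MAX}"
        )

    header = dict(frame.header)
    header["HEADER_BYTES"] = str(HEADER_BYTES)
    header["DIM"] = header.get("DIM", "2")
    header["TYPE"] = "unsigned_short"
    header["BYTE_ORDER"] = byte_order
    header["SIZE1"] = str(frame.n_fast)
    header["SIZE2"] = str(frame.n_slow)
    header["ADCOFFSET"] = str(int(offset))

    lines = "".join(f"{k}={v};\n" for k, v in header.items())
    text = "{\n" + lines + "}\n"
    raw = text.encode("ascii")
    if len(raw) > HEADER_BYTES:
        raise SMVFormatError(
            f"header of {len(raw)} bytes exceeds HEADER_BYTES={HEADER_BYTES}"
        )
    raw = raw.ljust(HEADER_BYTES, b"\x00")

    dtype = np.dtype("<u2") if byte_order == "little_endian" else np.dtype(">u2")
    payload = (pixels + offset).astype(dtype)
    with open(path, "wb") as fh:
        fh.write(raw)
        fh.write(payload.tobytes())


def apply_adc_offset(frame: ImageFrame) -> ImageFrame:
    """Subtract the header ADCOFFSET, recovering signed counts in memory."""
    offset = int(frame.header.get("ADCOFFSET", "0"))
    out = frame.copy()
    if offset:
        out.pixels = out.pixels.astype(np.int32) - offset
        out.signed = True
    return out


def mask_from_frame(mask_frame: ImageFrame) -> np.ndarray:
    """Interpret a 0/1-valued SMV image as a validity mask (1 = valid)."""
    return np.asarray(mask_frame.pixels) != 0
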