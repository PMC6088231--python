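"""Codec for mzML binary data arrays.

mzML stores peak vectors as base64 text wrapping little-endian IEEE floats
(32- or 64-bit), optionally zlib-compressed.  This module implements both
directions; the descriptor says how a given array is encoded and which
spectral role (m/z, intensity, noise, charge) it plays.
"""

from __future__ import annotations

import base64
import binascii
import zlib
from dataclasses import dataclass

import numpy as np

__all__ = ["BinaryArrayDescriptor", "CodecError", "TruncationError",
           "decode_binary_array", "encode_binary_array"]


class CodecError(ValueError):
    """Invalid base64, corrupt zlib stream, or unencodable input."""


class TruncationError(CodecError):
    """Decoded byte count is not a multiple of the element size."""


@dataclass(frozen=True)
class BinaryArrayDescriptor:
    """How one binary data array is encoded and what it carries.

    ``role`` is one of ``mz | intensity | noise | charge | other``; for
    ``other`` the originating CV accession is kept in ``accession``.
    """

    role: str
    precision: int = 64  # bits per float: 32 or 64
    compression: str = "none"  # "none" | "zlib"
    encoded_length: int | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        if self.precision not in (32, 64):
            raise ValueError(f"precision must be 32 or 64, got {self.precision}")
        if self.compression not in ("none", "zlib"):
            raise ValueError(f"unsupported compression {self.compression!r}")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype("<f4" if self.precision == 32 else "<f8")


def decode_binary_array(b64: str | bytes, desc: BinaryArrayDescriptor) -> np.ndarray:
    """Decode base64 text to a float64 vector per *desc*.

    32-bit values are widened to 64-bit on return.  Empty input yields an
    empty vector.
    """
    if isinstance(b64, str):
        b64 = b64.encode("ascii")
    try:
        raw = base64.b64decode(b64, validate=True)
    except (binascii.Error, ValueError) as exc:
        raise CodecError(f"invalid base64: {exc}") from exc
    if desc.compression == "zlib" and raw:
        try:
            raw = zlib.decompress(raw)
        except zlib.error as exc:
            raise CodecError(f"corrupt zlib stream: {exc}") from exc
    itemsize = desc.precision // 8
    if len(raw) % itemsize:
        raise TruncationError(
            f"{len(raw)} bytes is not a multiple of the {itemsize}-byte element size"
        )
    return np.frombuffer(raw, dtype=desc.dtype).astype(np.float64)


def encode_binary_array(values, desc: BinaryArrayDescriptor) -> str:
    """Encode a numeric vector as base64 text per *desc*.

    Inverse of :func:`decode_binary_array` at the descriptor's precision.
    Raises :class:`CodecError` on non-finite input or 32-bit overflow.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size and not np.all(np.isfinite(arr)):
        raise CodecError("non-finite values cannot be encoded")
    with np.errstate(over="ignore"):  # overflow is reported as a CodecError
        out = arr.astype(desc.dtype)
    if desc.precision == 32 and arr.size and not np.all(np.isfinite(out)):
        raise CodecError("value overflows 32-bit float range")
    raw = out.tobytes()
    if desc.compression == "zlib" and raw:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")
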