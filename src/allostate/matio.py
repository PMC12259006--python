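"""A minimal binary matrix container for feature matrices and discrete trajectories.

Layout: a 4-byte magic (``AMTX`` for float64 matrices, ``ADTJ`` for int64
vectors), a little-endian uint64 rank, the little-endian uint64 shape, then
the row-major payload (little-endian float64 or int64).
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["save_matrix", "load_matrix", "save_dtraj", "load_dtraj"]

_MAGIC_MAT = b"AMTX"
_MAGIC_DTJ = b"ADTJ"


def _write(path: str | Path, magic: bytes, arr: np.ndarray, dtype: str) -> None:
    arr = np.ascontiguousarray(arr.astype(dtype))
    with open(path, "wb") as fh:
        fh.write(magic)
        fh.write(struct.pack("<Q", arr.ndim))
        fh.write(struct.pack(f"<{arr.ndim}Q", *arr.shape))
        fh.write(arr.tobytes())


def _read(path: str | Path, magic: bytes, dtype: str) -> np.ndarray:
    with open(path, "rb") as fh:
        got = fh.read(4)
        if got != magic:
            raise ValueError(f"{path}: bad magic {got!r}, expected {magic!r}")
        (ndim,) = struct.unpack("<Q", fh.read(8))
        shape = struct.unpack(f"<{ndim}Q", fh.read(8 * ndim))
        data = np.frombuffer(fh.read(), dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise ValueError(f"{path}: payload size does not match header shape {shape}")
    return data.reshape(shape).copy()


def save_matrix(path: str | Path, values: np.ndarray) -> None:
    """Write a 2-D float64 matrix."""
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("save_matrix expects a 2-D array")
    _write(path, _MAGIC_MAT, values, "<f8")


def load_matrix(path: str | Path) -> np.ndarray:
    return _read(path, _MAGIC_MAT, "<f8")


def save_dtraj(path: str | Path, states: np.ndarray) -> None:
    """Write a 1-D int64 discrete trajectory."""
    states = np.asarray(states)
    if states.ndim != 1:
        raise ValueError("save_dtraj expects a 1-D array")
    _write(path, _MAGIC_DTJ, states, "<i8")


def load_dtraj(path: str | Path) -> np.ndarray:
    return _read(path, _MAGIC_DTJ, "<i8").astype(np.int64)
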