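"""Minimal MRC2014 volume / stack reader and writer.

Implements the subset of the MRC2014 standard this package needs: modes 0
(int8), 1 (int16), 2 (float32) and 6 (uint16), little-endian, no extended
header on write (skipped on read), voxel size carried in the cell
dimensions.  Data axis order on disk is the MRC default (x fastest), which
matches the ``[z, y, x]`` numpy layout used by :class:`DensityVolume`.
"""

from __future__ import annotations

import struct

import numpy as np

HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_DTYPE_MODES = {np.dtype(v): k for k, v in _MODE_DTYPES.items()}


class MRCParseError(ValueError):
    """Raised when a file does not parse as MRC2014."""


def write_mrc(path, data: np.ndarray, voxel_size: float = 1.0) -> None:
    """Write a 3D array as an MRC2014 file (2D arrays get nz=1)."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("MRC data must be 2D or 3D")
    dt = data.dtype
    if dt not in _DTYPE_MODES:
        if np.issubdtype(dt, np.floating):
            data, dt = data.astype(np.float32), np.dtype(np.float32)
        elif np.issubdtype(dt, np.integer):
            data, dt = data.astype(np.int16), np.dtype(np.int16)
        else:
            raise ValueError(f"unsupported dtype {dt}")
    mode = _DTYPE_MODES[np.dtype(dt)]
    nz, ny, nx = data.shape
    hdr = bytearray(HEADER_SIZE)
    struct.pack_into("<3i", hdr, 0, nx, ny, nz)           # NX NY NZ
    struct.pack_into("<i", hdr, 12, mode)                 # MODE
    struct.pack_into("<3i", hdr, 28, nx, ny, nz)          # MX MY MZ
    struct.pack_into("<3f", hdr, 40, nx * voxel_size, ny * voxel_size, nz * voxel_size)
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)    # cell angles
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)             # MAPC MAPR MAPS
    dmin, dmax = float(data.min()), float(data.max())
    dmean = float(data.mean(dtype=np.float64))
    struct.pack_into("<3f", hdr, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", hdr, 88, 1, 0)                # ISPG, NSYMBT
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes([0x44, 0x44, 0x00, 0x00])        # little-endian stamp
    struct.pack_into("<f", hdr, 216, float(data.std(dtype=np.float64)))
    struct.pack_into("<i", hdr, 220, 1)                   # NLABL
    hdr[224:224 + 30] = b"conetomo minimal MRC2014 write"
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(np.ascontiguousarray(data).astype(data.dtype.newbyteorder("<")).tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC2014 file; returns ``(data[z, y, x], voxel_size_x)``."""
    with open(path, "rb") as fh:
        hdr = fh.read(HEADER_SIZE)
        if len(hdr) < HEADER_SIZE:
            raise MRCParseError(
                f"truncated MRC header: got {len(hdr)} of {HEADER_SIZE} bytes"
            )
        nx, ny, nz = struct.unpack_from("<3i", hdr, 0)
        (mode,) = struct.unpack_from("<i", hdr, 12)
        if hdr[208:212] not in (b"MAP ", b"MAP\x00"):
            raise MRCParseError("missing 'MAP ' signature at word 53")
        if mode not in _MODE_DTYPES:
            raise MRCParseError(f"unsupported MRC mode {mode}")
        if min(nx, ny, nz) <= 0:
            raise MRCParseError(f"bad dimensions ({nx}, {ny}, {nz})")
        (mx,) = struct.unpack_from("<i", hdr, 28)
        (xlen,) = struct.unpack_from("<f", hdr, 40)
        voxel = xlen / mx if mx > 0 and xlen > 0 else 1.0
        (nsymbt,) = struct.unpack_from("<i", hdr, 92)
        if nsymbt > 0:
            fh.seek(nsymbt, 1)
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        count = nx * ny * nz
        raw = fh.read(count * dtype.itemsize)
        if len(raw) < count * dtype.itemsize:
            raise MRCParseError("truncated MRC data block")
        data = np.frombuffer(raw, dtype=dtype, count=count).reshape(nz, ny, nx)
    return data.astype(_MODE_DTYPES[mode]), float(voxel)
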