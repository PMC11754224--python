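"""Minimal LAS 1.2 reader/writer for XYZ coordinates.

Handles uncompressed ASPRS LAS versions 1.0-1.4 headers and point record
formats 0-3 (the fixed-layout formats whose first 12 bytes are the int32
X, Y, Z triplet). Header scale and offset are applied on read so coordinates
come out in meters; writing uses point format 0 with a 0.001 m scale and an
offset at the floor of the minimum coordinate. LAZ (compressed) input is
rejected.
"""

from __future__ import annotations

import struct

import numpy as np

_HEADER_FMT = "<4sHHL HH8sBB 32s 32s HHH LLBHL 5L dddddd dddddd"
# point record length of the standard fixed formats 0..5
_POINT_SIZES = {0: 20, 1: 28, 2: 26, 3: 34, 4: 57, 5: 63}


def read_las(path) -> np.ndarray:
    """Read XYZ coordinates (meters) from an uncompressed LAS file."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 227:
        raise ValueError(f"{path}: truncated LAS header")
    sig = data[:4]
    if sig == b"LASZ" or (len(data) > 100 and b"laszip" in data[:2000].lower()):
        raise ValueError(f"{path}: LAZ-compressed input is not supported")
    if sig != b"LASF":
        raise ValueError(f"{path}: not a LAS file (bad signature {sig!r})")
    ver_major, ver_minor = data[24], data[25]
    header_size = struct.unpack_from("<H", data, 94)[0]
    offset_to_points = struct.unpack_from("<L", data, 96)[0]
    fmt_id = data[104]
    if fmt_id & 0x80:
        raise ValueError(f"{path}: LAZ-compressed point format is not supported")
    point_len = struct.unpack_from("<H", data, 105)[0]
    n_points = struct.unpack_from("<L", data, 107)[0]
    if ver_major == 1 and ver_minor >= 4 and n_points == 0:
        n_points = struct.unpack_from("<Q", data, 247)[0]
    if fmt_id not in _POINT_SIZES:
        raise ValueError(f"{path}: unsupported point format {fmt_id}")
    if point_len < 12:
        raise ValueError(f"{path}: point record too short ({point_len})")
    sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", data, 131)
    if n_points < 1:
        raise ValueError(f"{path}: LAS file contains no points")
    end = offset_to_points + n_points * point_len
    if end > len(data):
        raise ValueError(f"{path}: truncated point data")
    raw = np.frombuffer(
        data, dtype=np.uint8, count=n_points * point_len, offset=offset_to_points
    ).reshape(n_points, point_len)
    ixyz = raw[:, :12].copy().view("<i4").reshape(n_points, 3).astype(np.float64)
    xyz = ixyz * np.array([sx, sy, sz]) + np.array([ox, oy, oz])
    return xyz


def write_las(path, xyz: np.ndarray, scale: float = 0.001) -> None:
    """Write XYZ coordinates (meters) as LAS 1.2, point format 0."""
    xyz = np.asarray(xyz, dtype=np.float64)
    n = xyz.shape[0]
    if n < 1:
        raise ValueError("refusing to write an empty LAS file")
    offset = np.floor(xyz.min(axis=0))
    ixyz = np.round((xyz - offset) / scale).astype("<i4")
    header_size = 227
    header = struct.pack(
        _HEADER_FMT,
        b"LASF",  # signature
        0,  # file source id
        0,  # global encoding
        0, 0, 0, b"\0" * 8,  # project GUID
        1, 2,  # version 1.2
        b"treedenoise".ljust(32, b"\0"),  # system id
        b"treedenoise writer".ljust(32, b"\0"),  # generating software
        1, 1970,  # day/year placeholders
        header_size,
        header_size,  # offset to point data (no VLRs)
        0,  # number of VLRs
        0, 20,  # point format 0, 20 bytes
        n,
        n, 0, 0, 0, 0,  # points by return (put all in return 1)
        scale, scale, scale,
        offset[0], offset[1], offset[2],
        float(xyz[:, 0].max()), float(xyz[:, 0].min()),
        float(xyz[:, 1].max()), float(xyz[:, 1].min()),
        float(xyz[:, 2].max()), float(xyz[:, 2].min()),
    )
    assert len(header) == header_size
    rec = np.zeros(n, dtype=[("xyz", "<i4", 3), ("rest", "u1", 8)])
    rec["xyz"] = ixyz
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())
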