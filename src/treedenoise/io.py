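"""Reading and writing point clouds: XYZ text, PLY, and LAS.

All readers return a raw-frame :class:`~treedenoise.cloud.PointCloud` with
point order exactly as stored. XYZ is whitespace-separated text with at least
three numeric columns ('#' lines are comments; extra columns are kept as
per-point attributes). PLY goes through :mod:`trimesh` (ASCII and binary).
LAS uses the in-package 1.2 codec with header scale/offset honored.
"""

from __future__ import annotations

import os

import numpy as np

from . import _las
from .cloud import PointCloud

__all__ = ["read_point_cloud", "write_point_cloud"]

_EXT_FORMAT = {
    ".xyz": "xyz",
    ".txt": "xyz",
    ".ply": "ply",
    ".las": "las",
    ".laz": "las",
}


def _resolve_format(path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _EXT_FORMAT:
        raise ValueError(f"cannot infer point-cloud format from extension {ext!r}")
    return _EXT_FORMAT[ext]


def _read_xyz(path):
    coords, extras, n_extra = [], [], None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 numeric fields, "
                    f"got {len(fields)}"
                )
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            coords.append(values[:3])
            extra = values[3:]
            if n_extra is None:
                n_extra = len(extra)
            elif len(extra) != n_extra:
                raise ValueError(
                    f"{path}: line {lineno}: inconsistent column count"
                )
            extras.append(extra)
    if not coords:
        raise ValueError(f"{path}: no points found")
    pts = np.asarray(coords, dtype=np.float64)
    attrs = {}
    if n_extra:
        extra_arr = np.asarray(extras, dtype=np.float64)
        attrs = {f"col{3 + j}": extra_arr[:, j] for j in range(n_extra)}
    return pts, attrs


def _read_ply(path):
    import trimesh

    loaded = trimesh.load(str(path), process=False)
    pts = np.asarray(loaded.vertices, dtype=np.float64)
    if pts.size == 0:
        raise ValueError(f"{path}: PLY file contains no vertices")
    return pts, {}


def _write_ply_double(path, pts: np.ndarray) -> None:
    # double-precision vertices so write->read round-trips below 1e-9
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {pts.shape[0]}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(pts, dtype="<f8").tobytes())


def read_point_cloud(path, format: str = "auto") -> PointCloud:
    """Read a point cloud file into a raw-frame :class:`PointCloud`.

    Parameters
    ----------
    path : path-like
    format : {"auto", "xyz", "ply", "las"}
        ``auto`` resolves from the file extension.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    if fmt == "xyz":
        pts, attrs = _read_xyz(path)
    elif fmt == "ply":
        pts, attrs = _read_ply(path)
    elif fmt == "las":
        pts, attrs = _las.read_las(path), {}
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not np.isfinite(pts).all():
        raise ValueError(f"{path}: non-finite coordinate")
    return PointCloud(points=pts, frame="raw", attrs=attrs)


def write_point_cloud(cloud: PointCloud, path, format: str = "auto") -> None:
    """Write a cloud to disk in the requested (or extension-implied) format.

    LAS output is quantized to a 0.001 m grid (the written coordinate scale);
    XYZ and PLY are lossless to float precision.
    """
    fmt = _resolve_format(path, format)
    pts = cloud.points
    if fmt == "xyz":
        cols = [pts] + [np.asarray(v).reshape(-1, 1) for v in cloud.attrs.values()]
        np.savetxt(path, np.hstack(cols), fmt="%.10g")
    elif fmt == "ply":
        _write_ply_double(path, pts)
    elif fmt == "las":
        _las.write_las(path, pts)
    else:
        raise ValueError(f"unknown format {fmt!r}")
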