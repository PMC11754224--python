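"""Point-cloud container, unit-sphere normalization, and fixed-size subsampling.

A :class:`PointCloud` is an ordered ``n x 3`` array of coordinates plus a frame
tag. Raw-frame clouds carry meters; normalized clouds are centroid-centered and
scaled so the farthest point sits at radius 1, which makes noise levels (e.g.
sigma = 0.1) interpretable as a fraction of the object radius. Every operation
here preserves point order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PointCloud",
    "NormalizationRecord",
    "normalize",
    "denormalize",
    "sample_fixed",
]


@dataclass(frozen=True)
class NormalizationRecord:
    """Invertible record of a unit-sphere normalization.

    ``normalized = (raw - centroid) / scale``; ``scale`` is the maximum
    centroid distance of the raw cloud, in meters.
    """

    centroid: np.ndarray
    scale: float

    def __post_init__(self):
        c = np.asarray(self.centroid, dtype=np.float64).reshape(3)
        object.__setattr__(self, "centroid", c)
        if not np.isfinite(c).all():
            raise ValueError("non-finite centroid")
        if not (self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale}")


@dataclass(frozen=True)
class PointCloud:
    """An ordered set of 3-D points with a coordinate-frame tag.

    Parameters
    ----------
    points : (n, 3) float array
        Coordinates; meters in the ``raw`` frame, unitless in ``normalized``.
    frame : {"raw", "normalized"}
    norm : NormalizationRecord, optional
        Present iff ``frame == "normalized"``; the inverse transform.
    attrs : dict of name -> (n,) array, optional
        Per-point scalars (intensity, labels, ...) carried through untouched.
    """

    points: np.ndarray
    frame: str = "raw"
    norm: NormalizationRecord | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("a point cloud needs at least one point")
        if not np.isfinite(pts).all():
            raise ValueError("non-finite coordinate in point cloud")
        object.__setattr__(self, "points", pts)
        if self.frame not in ("raw", "normalized"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.frame == "normalized":
            if self.norm is None:
                raise ValueError("normalized frame requires a NormalizationRecord")
            r = np.linalg.norm(pts, axis=1).max()
            if r > 1 + 1e-9:
                raise ValueError(f"normalized cloud has radius {r} > 1")
        for k, v in self.attrs.items():
            if len(np.asarray(v)) != pts.shape[0]:
                raise ValueError(f"attr {k!r} length mismatch")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """Same frame/record/attrs, new coordinates (same n)."""
        return replace(self, points=points)

    def take(self, indices: np.ndarray) -> "PointCloud":
        """Subset by index array, preserving the given order."""
        idx = np.asarray(indices)
        return replace(
            self,
            points=self.points[idx],
            attrs={k: np.asarray(v)[idx] for k, v in self.attrs.items()},
        )


def normalize(cloud: PointCloud) -> PointCloud:
    """Center at the centroid and scale to the unit sphere.

    The output's farthest point from the origin sits at radius exactly 1 and
    the inverse transform is stored on the cloud. Rejects all-coincident
    clouds, whose scale would be zero.
    """
    if cloud.frame != "raw":
        raise ValueError("normalize expects a raw-frame cloud")
    centroid = cloud.points.mean(axis=0)
    centered = cloud.points - centroid
    scale = float(np.linalg.norm(centered, axis=1).max())
    if scale == 0.0:
        raise ValueError("cannot normalize: all points coincident")
    return PointCloud(
        points=centered / scale,
        frame="normalized",
        norm=NormalizationRecord(centroid=centroid, scale=scale),
        attrs=dict(cloud.attrs),
    )


def denormalize(cloud: PointCloud) -> PointCloud:
    """Invert :func:`normalize`: ``raw = p * scale + centroid``."""
    if cloud.frame != "normalized" or cloud.norm is None:
        raise ValueError("denormalize expects a normalized cloud with a record")
    rec = cloud.norm
    return PointCloud(
        points=cloud.points * rec.scale + rec.centroid,
        frame="raw",
        attrs=dict(cloud.attrs),
    )


def _farthest_point_indices(pts: np.ndarray, n_out: int, start: int) -> np.ndarray:
    """Greedy farthest-point sampling from a chosen start index."""
    n = pts.shape[0]
    chosen = np.empty(n_out, dtype=np.intp)
    chosen[0] = start
    dist = np.linalg.norm(pts - pts[start], axis=1)
    for i in range(1, n_out):
        nxt = int(np.argmax(dist))
        chosen[i] = nxt
        dist = np.minimum(dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return chosen


def sample_fixed(
    cloud: PointCloud, n_out: int, strategy: str = "random", seed: int = 0
) -> PointCloud:
    """Deterministically subsample to exactly ``n_out`` points.

    ``random`` draws a uniform subset without replacement, returned in input
    order; ``fps`` runs farthest-point sampling from a seed-chosen start index,
    returned in selection order. The result is always a subset of the input
    points and is bit-reproducible given the seed.
    """
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    if n_out > cloud.n:
        raise ValueError(f"n_out={n_out} exceeds cloud size {cloud.n}")
    if n_out == cloud.n:
        return cloud
    rng = np.random.default_rng(seed)
    if strategy == "random":
        idx = np.sort(rng.choice(cloud.n, size=n_out, replace=False))
    elif strategy == "fps":
        start = int(rng.integers(cloud.n))
        idx = _farthest_point_indices(cloud.points, n_out, start)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return cloud.take(idx)
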