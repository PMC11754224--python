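"""Classical outlier filters for like-for-like comparison with the denoiser.

Statistical Outlier Removal (SOR) thresholds each point's mean k-NN distance
at the global mean + n_sigma * std of those values; Radius Outlier Removal
(ROR) drops points with too few neighbors inside a fixed radius. Both are
deterministic, keep surviving points untouched and in order, and report the
removed indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = ["FilterResult", "sor_filter", "ror_filter"]


@dataclass(frozen=True)
class FilterResult:
    kept: PointCloud
    removed_indices: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "removed_indices", np.asarray(self.removed_indices, dtype=np.intp)
        )


def sor_filter(cloud: PointCloud, k: int = 8, n_sigma: float = 1.0) -> FilterResult:
    """Statistical outlier removal.

    Removes points whose mean distance to their ``k`` nearest other points
    exceeds ``mean + n_sigma * std`` of that statistic over the cloud.
    """
    if k >= cloud.n:
        raise ValueError(f"k={k} must be < n={cloud.n}")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)  # first column is self
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + n_sigma * mean_d.std()
    removed = np.flatnonzero(mean_d > thresh)
    kept_idx = np.flatnonzero(mean_d <= thresh)
    if kept_idx.size == 0:
        raise ValueError("SOR removed every point; loosen n_sigma")
    return FilterResult(kept=cloud.take(kept_idx), removed_indices=removed)


def ror_filter(cloud: PointCloud, radius: float, min_neighbors: int = 1) -> FilterResult:
    """Radius outlier removal.

    Removes points with fewer than ``min_neighbors`` other points within
    ``radius``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if min_neighbors < 0:
        raise ValueError("min_neighbors must be >= 0")
    tree = cKDTree(cloud.points)
    counts = np.array(
        [len(nb) - 1 for nb in tree.query_ball_point(cloud.points, r=radius)]
    )
    removed = np.flatnonzero(counts < min_neighbors)
    kept_idx = np.flatnonzero(counts >= min_neighbors)
    if kept_idx.size == 0:
        raise ValueError("ROR removed every point; loosen parameters")
    return FilterResult(kept=cloud.take(kept_idx), removed_indices=removed)
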