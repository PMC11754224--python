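"""Synthetic clean fixtures: single trees, mini forest plots, and primitives.

LiDAR returns come from surfaces, so every generator samples surfaces (not
volumes): a tree is a cylinder-surface trunk plus an ellipsoid-surface crown,
a plot scatters trees over a square with minimum spacing and an optional
ground plane, and primitives (unit sphere / plane / cylinder) provide
analytically known geometry for denoising recovery tests. All generators are
deterministic given their seed and return clean, noise-free clouds with
per-point labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud

__all__ = ["TreeParams", "SceneTruth", "generate_tree", "generate_plot", "generate_primitive"]

LABELS = {"trunk": 0, "crown": 1, "ground": 2, "outlier": 3}


@dataclass(frozen=True)
class TreeParams:
    """Geometry and sampling budget of one synthetic tree (meters)."""

    trunk_height: float = 8.0
    trunk_radius: float = 0.25
    crown_radii: tuple = (2.5, 2.5, 3.5)
    crown_center_height: float = 9.0
    n_trunk: int = 512
    n_crown: int = 1536
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "crown_radii", tuple(float(r) for r in self.crown_radii))
        if min(self.trunk_height, self.trunk_radius, *self.crown_radii) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.n_trunk < 0 or self.n_crown < 0 or self.n_trunk + self.n_crown < 1:
            raise ValueError("need at least one point")


@dataclass(frozen=True)
class SceneTruth:
    """A clean cloud plus per-point semantic labels and per-tree ids."""

    clean: PointCloud
    labels: np.ndarray
    tree_ids: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        ids = np.asarray(self.tree_ids)
        if len(labels) != self.clean.n or len(ids) != self.clean.n:
            raise ValueError("labels/tree_ids must align with the cloud")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "tree_ids", ids)


def _cylinder_surface(n, radius, height, rng):
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, height, n)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])


def _ellipsoid_surface(n, radii, rng):
    # isotropic directions stretched to the semi-axes; area-exact uniformity is
    # not needed for fixtures, angular uniformity is enough
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * np.asarray(radii)


def generate_tree(params: TreeParams) -> SceneTruth:
    """Sample one tree: trunk on a z-axis cylinder surface, crown on an
    ellipsoid surface centered at ``crown_center_height``."""
    rng = np.random.default_rng(params.seed)
    parts, labels = [], []
    if params.n_trunk:
        parts.append(_cylinder_surface(params.n_trunk, params.trunk_radius,
                                       params.trunk_height, rng))
        labels.append(np.full(params.n_trunk, LABELS["trunk"]))
    if params.n_crown:
        crown = _ellipsoid_surface(params.n_crown, params.crown_radii, rng)
        crown[:, 2] += params.crown_center_height
        parts.append(crown)
        labels.append(np.full(params.n_crown, LABELS["crown"]))
    pts = np.vstack(parts)
    lab = np.concatenate(labels)
    return SceneTruth(
        clean=PointCloud(points=pts, frame="raw", attrs={"label": lab}),
        labels=lab,
        tree_ids=np.zeros(pts.shape[0], dtype=np.intp),
    )


def generate_plot(
    n_trees: int,
    area_side: float = 40.0,
    params: TreeParams = TreeParams(),
    min_spacing: float = 4.0,
    n_ground: int = 0,
    seed: int = 0,
) -> SceneTruth:
    """Scatter ``n_trees`` trees over a square plot with minimum spacing.

    Tree centers are drawn uniformly with rejection until pairwise spacing
    holds (error after 10000 failed proposals). Optional ground points sample
    the z=0 plane.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    centers = []
    attempts = 0
    while len(centers) < n_trees:
        c = rng.uniform(0, area_side, 2)
        if all(np.hypot(*(c - p)) >= min_spacing for p in centers):
            centers.append(c)
        else:
            attempts += 1
            if attempts > 10000:
                raise ValueError(
                    f"cannot place {n_trees} trees with spacing {min_spacing} "
                    f"in a {area_side} m square"
                )
    parts, labels, ids = [], [], []
    for t, c in enumerate(centers):
        tree = generate_tree(
            TreeParams(**{**params.__dict__, "seed": int(rng.integers(2**31))})
        )
        pts = tree.clean.points + np.array([c[0], c[1], 0.0])
        parts.append(pts)
        labels.append(tree.labels)
        ids.append(np.full(pts.shape[0], t, dtype=np.intp))
    if n_ground:
        g = np.column_stack([
            rng.uniform(0, area_side, n_ground),
            rng.uniform(0, area_side, n_ground),
            np.zeros(n_ground),
        ])
        parts.append(g)
        labels.append(np.full(n_ground, LABELS["ground"]))
        ids.append(np.full(n_ground, -1, dtype=np.intp))
    pts = np.vstack(parts)
    lab = np.concatenate(labels)
    tid = np.concatenate(ids)
    return SceneTruth(
        clean=PointCloud(points=pts, frame="raw", attrs={"label": lab, "tree_id": tid}),
        labels=lab,
        tree_ids=tid,
    )


def generate_primitive(shape: str, n: int, seed: int = 0) -> PointCloud:
    """Uniform surface samples of a unit-scale primitive.

    ``sphere``: unit radius centered at the origin. ``plane``: the z=0 unit
    square [0,1]^2. ``cylinder``: unit radius and unit height, axis = z.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if shape == "sphere":
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v
    elif shape == "plane":
        pts = np.column_stack([rng.uniform(0, 1, n), rng.uniform(0, 1, n), np.zeros(n)])
    elif shape == "cylinder":
        pts = _cylinder_surface(n, 1.0, 1.0, rng)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return PointCloud(points=pts, frame="raw")
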