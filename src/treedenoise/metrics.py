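"""Point-cloud denoising evaluation: MSE, SNR, one-way Hausdorff, 3-D SSIM.

The quartet covers complementary failure modes: MSE measures mean squared
per-point residual (accuracy), SNR expresses it against the reference
signal power in decibels (clarity), the one-way Hausdorff distance captures
the worst-case geometric deviation, and the neighborhood-based 3-D SSIM
scores preservation of local structure. Correspondence between estimate and
reference points is either ``paired`` (index-aligned, equal sizes) or
``nearest`` (each estimate point matched to its nearest reference point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import directed_hausdorff

from .cloud import PointCloud

__all__ = [
    "Correspondence",
    "MetricReport",
    "build_correspondence",
    "pc_mse",
    "pc_snr",
    "hausdorff_oneway",
    "hausdorff_symmetric",
    "ssim3d",
    "evaluate",
]


@dataclass(frozen=True)
class Correspondence:
    """Mapping from estimate points into the reference cloud."""

    mode: str
    mapping: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mapping", np.asarray(self.mapping, dtype=np.intp))


def build_correspondence(reference: PointCloud, estimate: PointCloud, mode: str = "paired") -> Correspondence:
    """``paired``: identity mapping (requires equal sizes). ``nearest``: each
    estimate point maps to its nearest reference point (ties by lower index in
    the brute-force sense; continuous data has no ties)."""
    if mode == "paired":
        if reference.n != estimate.n:
            raise ValueError(
                f"paired correspondence needs equal sizes ({reference.n} vs {estimate.n})"
            )
        return Correspondence(mode="paired", mapping=np.arange(reference.n))
    if mode == "nearest":
        tree = cKDTree(reference.points)
        _, idx = tree.query(estimate.points, k=1)
        return Correspondence(mode="nearest", mapping=idx)
    raise ValueError(f"unknown correspondence mode {mode!r}")


def pc_mse(reference: PointCloud, estimate: PointCloud, corr: Correspondence) -> float:
    """Mean over matched pairs of the squared Euclidean point distance."""
    ref = reference.points[corr.mapping]
    resid = estimate.points - ref
    return float(np.mean(np.sum(resid * resid, axis=1)))


def pc_snr(reference: PointCloud, estimate: PointCloud, corr: Correspondence) -> float:
    """Signal-to-noise ratio in dB: 10*log10(Ps / Pn).

    Ps is the reference cloud's mean squared point norm in its stored frame;
    Pn is :func:`pc_mse`. Returns +inf for a perfect estimate.
    """
    ps = float(np.mean(np.sum(reference.points**2, axis=1)))
    pn = pc_mse(reference, estimate, corr)
    if pn == 0.0:
        return float("inf")
    return float(10.0 * np.log10(ps / pn))


def hausdorff_oneway(A: PointCloud, B: PointCloud) -> float:
    """Forward Hausdorff distance: max over a in A of min over b in B of |a-b|."""
    d, _, _ = directed_hausdorff(A.points, B.points)
    return float(d)


def hausdorff_symmetric(A: PointCloud, B: PointCloud) -> float:
    """max(h(A, B), h(B, A))."""
    return max(hausdorff_oneway(A, B), hausdorff_oneway(B, A))


def _local_signal(tree: cKDTree, pts: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    """Sorted vector of neighbor distances to the neighborhood centroid.

    Rotation- and translation-invariant descriptor of the local point
    arrangement around a query position.
    """
    _, idx = tree.query(query, k=k)
    nb = pts[np.atleast_1d(idx)]
    centroid = nb.mean(axis=0)
    return np.sort(np.linalg.norm(nb - centroid, axis=1))


def ssim3d(
    reference: PointCloud,
    estimate: PointCloud,
    corr: Correspondence,
    k_ssim: int = 16,
    K1: float = 0.01,
    K2: float = 0.03,
    L_range: float | None = None,
) -> float:
    """Neighborhood-based structural similarity between two clouds.

    For each correspondence pair, the local signal in each cloud is the sorted
    vector of k-NN distances to the neighborhood centroid around the pair's
    own point (reference point in the reference cloud, estimate point in the
    estimate cloud). The standard SSIM ratio with C1 = (K1*L)^2 and
    C2 = (K2*L)^2 is computed over the two matched signal vectors and averaged
    over pairs. L defaults to the reference bounding-box diagonal.
    """
    if k_ssim >= reference.n or k_ssim >= estimate.n:
        raise ValueError("k_ssim must be smaller than both cloud sizes")
    if L_range is None:
        bb = reference.points.max(axis=0) - reference.points.min(axis=0)
        L_range = float(np.linalg.norm(bb))
    if L_range <= 0:
        raise ValueError("L_range must be positive")
    C1 = (K1 * L_range) ** 2
    C2 = (K2 * L_range) ** 2
    ref_pts, est_pts = reference.points, estimate.points
    ref_tree, est_tree = cKDTree(ref_pts), cKDTree(est_pts)
    vals = np.empty(estimate.n)
    for i in range(estimate.n):
        x = _local_signal(ref_tree, ref_pts, ref_pts[corr.mapping[i]], k_ssim)
        y = _local_signal(est_tree, est_pts, est_pts[i], k_ssim)
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = ((x - mx) * (y - my)).mean()
        vals[i] = ((2 * mx * my + C1) * (2 * cxy + C2)) / (
            (mx * mx + my * my + C1) * (vx + vy + C2)
        )
    return float(vals.mean())


@dataclass(frozen=True)
class MetricReport:
    """The metric quartet plus the exact settings used to compute it."""

    mse: float
    snr_db: float
    hausdorff: float
    ssim: float
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "snr_db": self.snr_db,
            "hausdorff": self.hausdorff,
            "ssim": self.ssim,
            "params": dict(self.params),
        }


def compute_report(
    reference: PointCloud,
    estimate: PointCloud,
    mode: str = "paired",
    k_ssim: int = 16,
    K1: float = 0.01,
    K2: float = 0.03,
    L_range: float | None = None,
) -> MetricReport:
    """All four metrics of one estimate against a reference cloud."""
    corr = build_correspondence(reference, estimate, mode)
    return MetricReport(
        mse=pc_mse(reference, estimate, corr),
        snr_db=pc_snr(reference, estimate, corr),
        hausdorff=hausdorff_oneway(estimate, reference),
        ssim=ssim3d(reference, estimate, corr, k_ssim=k_ssim, K1=K1, K2=K2, L_range=L_range),
        params={
            "correspondence": mode,
            "k_ssim": k_ssim,
            "K1": K1,
            "K2": K2,
            "L_range": L_range,
            "frame": reference.frame,
        },
    )


def reports_to_csv(reports: list, path) -> None:
    """Batch evaluation CSV: one row per cloud plus mean/std footer rows."""
    cols = ("mse", "snr_db", "hausdorff", "ssim")
    rows = [[getattr(r, c) for c in cols] for r in reports]
    arr = np.asarray(rows, dtype=float)
    with open(path, "w") as fh:
        fh.write("cloud," + ",".join(cols) + "\n")
        for i, row in enumerate(rows):
            fh.write(str(i) + "," + ",".join(f"{v:.10g}" for v in row) + "\n")
        finite = np.where(np.isfinite(arr), arr, np.nan)
        fh.write("mean," + ",".join(f"{v:.10g}" for v in np.nanmean(finite, axis=0)) + "\n")
        fh.write("std," + ",".join(f"{v:.10g}" for v in np.nanstd(finite, axis=0)) + "\n")


def evaluate(
    reference: PointCloud,
    noisy: PointCloud,
    denoised: PointCloud,
    mode: str = "paired",
    k_ssim: int = 16,
    K1: float = 0.01,
    K2: float = 0.03,
    L_range: float | None = None,
):
    """Like-for-like reports for the noisy input and its denoised estimate.

    Both reports use identical settings and the reference's frame; the pair is
    JSON-serializable via ``to_dict``.
    """
    frames = {reference.frame, noisy.frame, denoised.frame}
    if len(frames) != 1:
        raise ValueError(f"frame mismatch among clouds: {sorted(frames)}")
    kw = dict(mode=mode, k_ssim=k_ssim, K1=K1, K2=K2, L_range=L_range)
    return compute_report(reference, noisy, **kw), compute_report(reference, denoised, **kw)
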