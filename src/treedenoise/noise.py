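"""Synthetic sensor noise and the double-noise training construction.

The unsupervised training scheme never sees a clean cloud. Given an observed
noisy cloud Pdot = P + N, it injects a second, independent noise draw M of the
same family and level to form the double-noisy cloud Pdot' = Pdot + M. Because
N and M are i.i.d., the conditional expectation of the clean-recovery
displacement from Pdot' equals twice the (known) single-noise displacement
ddot = Pdot - Pdot' = -M, so 2*ddot is a valid regression target even though
neither P nor N is ever observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud

__all__ = ["NoiseSpec", "DoubleNoisePair", "inject_noise", "make_double_noise_pair", "training_target"]

_SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive per-point noise specification, in normalized units.

    ``sigma`` is the per-axis standard deviation (gaussian: isotropic normal;
    uniform: per-axis on [-sigma*sqrt(3), sigma*sqrt(3)] so the per-axis std is
    also sigma). An ``outlier_fraction`` of points may additionally receive an
    isotropic gaussian kick of std ``sigma * outlier_scale`` to emulate sparse
    LiDAR outliers; it defaults to 0 and is then exactly the plain additive
    model.
    """

    family: str = "gaussian"
    sigma: float = 0.1
    outlier_fraction: float = 0.0
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("gaussian", "uniform"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.outlier_scale <= 0:
            raise ValueError("outlier_scale must be > 0")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "sigma": self.sigma,
            "outlier_fraction": self.outlier_fraction,
            "outlier_scale": self.outlier_scale,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(**d)


def _draw(spec: NoiseSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.family == "gaussian":
        noise = rng.normal(scale=spec.sigma, size=(n, 3)) if spec.sigma > 0 else np.zeros((n, 3))
    else:
        half = spec.sigma * _SQRT3
        noise = rng.uniform(-half, half, size=(n, 3))
    if spec.outlier_fraction > 0 and spec.sigma > 0:
        n_out = int(round(spec.outlier_fraction * n))
        if n_out:
            idx = rng.choice(n, size=n_out, replace=False)
            noise[idx] += rng.normal(scale=spec.sigma * spec.outlier_scale, size=(n_out, 3))
    return noise


def noise_draw(spec: NoiseSpec, n: int, seed: int | None = None) -> np.ndarray:
    """Draw an ``(n, 3)`` noise realization; seed defaults to ``spec.seed``."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    return _draw(spec, n, rng)


def inject_noise(
    cloud: PointCloud, spec: NoiseSpec, *, allow_raw: bool = False
) -> PointCloud:
    """Add one i.i.d. noise realization to every point.

    Noise levels are expressed in normalized units, so the input must be in
    the normalized frame unless ``allow_raw`` explicitly overrides. Order is
    preserved and the output is bit-reproducible given ``spec.seed``.
    """
    if cloud.frame != "normalized" and not allow_raw:
        raise ValueError(
            "inject_noise expects a normalized cloud (sigma is in normalized "
            "units); pass allow_raw=True to override"
        )
    noise = noise_draw(spec, cloud.n)
    pts = cloud.points + noise
    # perturbed points may leave the unit sphere, so the strict "normalized"
    # frame tag no longer applies; the coordinates stay in normalized units
    # and the inverse record is carried along for later denormalization
    return PointCloud(points=pts, frame="raw", norm=cloud.norm, attrs=dict(cloud.attrs))


@dataclass(frozen=True)
class DoubleNoisePair:
    """The training unit: base noisy cloud, injected noise M, and both views.

    Invariants hold exactly by construction: ``double = base + injected`` and
    ``d_dot = -injected`` (d_dot is the displacement from the double-noisy
    point back to its base point).
    """

    base: PointCloud
    injected: np.ndarray
    double: PointCloud
    d_dot: np.ndarray = field(init=False)

    def __post_init__(self):
        inj = np.asarray(self.injected, dtype=np.float64)
        if inj.shape != (self.base.n, 3):
            raise ValueError("injected noise shape mismatch")
        if self.double.n != self.base.n:
            raise ValueError("base/double size mismatch")
        object.__setattr__(self, "injected", inj)
        # defined as -injected (algebraically base - double) so the identity
        # d_dot = -M holds bit-exactly, not just to rounding
        object.__setattr__(self, "d_dot", -inj)

    @property
    def n(self) -> int:
        return self.base.n


def make_double_noise_pair(base: PointCloud, spec: NoiseSpec, seed: int) -> DoubleNoisePair:
    """Build a :class:`DoubleNoisePair` by injecting a fresh noise draw M.

    M's random stream is derived from ``seed`` alone, so it is independent of
    whatever produced the base cloud's noise.
    """
    injected = noise_draw(spec, base.n, seed=seed)
    double = PointCloud(
        points=base.points + injected, frame="raw", norm=base.norm, attrs=dict(base.attrs)
    )
    return DoubleNoisePair(base=base, injected=injected, double=double)


def export_pair(pair: DoubleNoisePair, base_path, double_path) -> None:
    """Write the base and double-noisy clouds as paired PLY files for
    inspection (same point order in both)."""
    from .io import write_point_cloud

    write_point_cloud(pair.base, base_path, format="ply")
    write_point_cloud(pair.double, double_path, format="ply")


def training_target(pair: DoubleNoisePair) -> np.ndarray:
    """The per-point regression target 2*d_dot = -2*M, aligned index-wise.

    This is the doubled displacement the network regresses against: the
    conditional-expectation identity makes twice the base-to-double
    displacement an unbiased surrogate for the unobservable clean-recovery
    displacement.
    """
    return 2.0 * pair.d_dot
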