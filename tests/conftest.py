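import numpy as np
import pytest

from treedenoise.cloud import PointCloud
from treedenoise.noise import NoiseSpec, noise_draw
from treedenoise.synthetic import generate_primitive


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    """200 uniform points in a unit box; no exact distance ties."""
    return PointCloud(rng.uniform(-1, 1, size=(200, 3)))


@pytest.fixture
def sphere_cloud():
    return generate_primitive("sphere", 512, seed=7)


@pytest.fixture
def noisy_sphere(sphere_cloud):
    M = noise_draw(NoiseSpec(sigma=0.02), sphere_cloud.n, seed=99)
    return PointCloud(sphere_cloud.points + M)


def brute_force_knn(pts: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive k-NN with self excluded, ties broken by lower index."""
    n = pts.shape[0]
    out = np.empty((n, k), dtype=np.intp)
    for i in range(n):
        d2 = np.sum((pts - pts[i]) ** 2, axis=1)
        d2[i] = np.inf
        out[i] = np.argsort(d2, kind="stable")[:k]
    return out


def brute_force_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """O(n^2) double-loop forward Hausdorff distance."""
    worst = 0.0
    for a in A:
        best = min(float(np.linalg.norm(a - b)) for b in B)
        worst = max(worst, best)
    return worst
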