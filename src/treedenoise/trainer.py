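"""Unsupervised training loop and inference for the displacement denoiser.

Training never sees a clean cloud: each step draws a fresh independent noise
realization M per sample, forms the double-noisy view, and regresses the
predicted displacement field onto 2*ddot = -2M, plus the pseudo-clean
repulsion term. The optimizer is Adam with L2 weight decay; the learning rate
follows cosine annealing from ``base_lr`` down to ``eta_min``. Everything is
reproducible from ``TrainConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud, sample_fixed
from .losses import LossConfig
from .network import (
    ModelConfig,
    backward_batch,
    forward_batch,
    init_model,
    knn_graph,
    predict_displacements,
)
from .noise import NoiseSpec, noise_draw

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "cosine_lr",
    "make_batches",
    "train",
    "denoise",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """All training hyperparameters.

    Defaults follow the full-scale recipe: lr 0.001 cosine-annealed to 1e-5,
    200 epochs, batches of 128 point sets of 2048 points, noise sigma 0.1
    (normalized units), repulsion weight 5e-4. ``desk()`` returns the reduced
    configuration used for CPU-scale fixtures and tests.
    """

    base_lr: float = 0.001
    lr_schedule: str = "cosine"
    eta_min: float = 1e-5
    epochs: int = 200
    batch_size: int = 128
    patch_points: int = 2048
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (self.base_lr > self.eta_min >= 0):
            raise ValueError("need base_lr > eta_min >= 0")
        if self.lr_schedule != "cosine":
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")

    @classmethod
    def desk(cls, *, sigma: float = 0.02, seed: int = 0) -> "TrainConfig":
        """Reduced preset for CPU-scale runs: 50 epochs, batch 8, whole
        2048-point fixture clouds as samples, 3-64-128-256 encoder."""
        return cls(
            epochs=50,
            batch_size=8,
            patch_points=2048,
            noise=NoiseSpec(sigma=sigma),
            model=ModelConfig(
                encoder_widths=(3, 64, 128, 256),
                decoder_widths=(128, 64, 3),
                seed=seed,
            ),
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {
            "base_lr": self.base_lr,
            "lr_schedule": self.lr_schedule,
            "eta_min": self.eta_min,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "patch_points": self.patch_points,
            "noise": self.noise.to_dict(),
            "loss": self.loss.to_dict(),
            "model": self.model.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "noise" in d:
            d["noise"] = NoiseSpec.from_dict(d["noise"])
        if "loss" in d:
            d["loss"] = LossConfig.from_dict(d["loss"])
        if "model" in d:
            d["model"] = ModelConfig.from_dict(d["model"])
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch training records: (epoch, lr, mean l_mse, mean l_rep, mean total)."""

    records: list = field(default_factory=list)

    def append(self, epoch: int, lr: float, l_mse: float, l_rep: float, total: float):
        self.records.append(
            {"epoch": epoch, "lr": lr, "l_mse": l_mse, "l_rep": l_rep, "total": total}
        )

    def __len__(self):
        return len(self.records)

    def column(self, name: str) -> np.ndarray:
        return np.array([r[name] for r in self.records])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,lr,l_mse,l_rep,total\n")
            for r in self.records:
                fh.write(
                    f"{r['epoch']},{r['lr']:.10g},{r['l_mse']:.10g},"
                    f"{r['l_rep']:.10g},{r['total']:.10g}\n"
                )


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """Cosine-annealed learning rate at an epoch index (0-based).

    ``eta_min + (base_lr - eta_min) * (1 + cos(pi * epoch / epochs)) / 2``.
    """
    if not 0 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} out of range [0, {config.epochs}]")
    cos = np.cos(np.pi * epoch / config.epochs)
    return float(config.eta_min + (config.base_lr - config.eta_min) * (1 + cos) / 2)


def _derived_seed(*parts: int) -> int:
    """Deterministic sub-seed below 2**31 from a tuple of integers."""
    ss = np.random.SeedSequence(entropy=list(parts))
    return int(ss.generate_state(1)[0] % (2**31))


def make_batches(dataset: list, config: TrainConfig, epoch: int) -> list:
    """Fixed-size point-set batches for one epoch.

    Each cloud contributes one ``patch_points``-point subset per epoch (drawn
    via random subsampling, seeded per cloud and epoch); cloud order is
    shuffled per epoch. Returns a list of (B, patch_points, 3) arrays; the
    final batch may be smaller when the dataset size is not a multiple of
    ``batch_size``.
    """
    patches = []
    for i, cloud in enumerate(dataset):
        if cloud.n < config.patch_points:
            raise ValueError(
                f"cloud {i} has {cloud.n} points < patch_points={config.patch_points}"
            )
        sub = sample_fixed(
            cloud, config.patch_points, strategy="random",
            seed=_derived_seed(config.seed, epoch, i, 0xA1),
        )
        patches.append(sub.points)
    order = np.random.default_rng(_derived_seed(config.seed, epoch, 0xB2)).permutation(
        len(patches)
    )
    batches = []
    for start in range(0, len(patches), config.batch_size):
        grp = order[start : start + config.batch_size]
        batches.append(np.stack([patches[j] for j in grp]))
    return batches


def _adam_init(params: dict) -> dict:
    zeros = lambda arrs: [np.zeros_like(a, dtype=np.float32) for a in arrs]
    return {
        "t": 0,
        "m": {k: zeros(v) for k, v in params.items()},
        "v": {k: zeros(v) for k, v in params.items()},
    }


def _adam_step(params, grads, state, lr, weight_decay, b1=0.9, b2=0.999, eps=1e-8):
    state["t"] += 1
    t = state["t"]
    for key in params:
        for i, (p, g) in enumerate(zip(params[key], grads[key])):
            g = np.asarray(g, dtype=np.float32)
            if weight_decay > 0 and key in ("enc_W", "dec_W"):
                g = g + weight_decay * p
            m = state["m"][key][i]
            v = state["v"][key][i]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)


def _batch_loss_and_grad(params, config: TrainConfig, batch: np.ndarray, pair_seed: int,
                         dropout_rng: np.random.Generator):
    """One training step's forward pass, loss components, and dD gradient."""
    B, n, _ = batch.shape
    spec = config.noise
    M = np.stack([noise_draw(spec, n, seed=_derived_seed(pair_seed, b)) for b in range(B)])
    double = batch + M
    target = -2.0 * M  # = 2 * d_dot
    idx = np.stack([knn_graph(double[b], config.model.k_feat) for b in range(B)])
    D, cache = forward_batch(
        params, config.model, double, idx,
        training=True, dropout_rng=dropout_rng, want_cache=True,
    )
    D = D.astype(np.float64)

    resid = D - target
    l_mse = float(np.sum(resid * resid) / (B * n))
    dD = 2.0 * resid / (B * n)

    gamma = config.loss.gamma
    k_rep = config.loss.k_rep
    l_rep = 0.0
    if gamma > 0:
        p_tilde = double + 2.0 * (-M)  # base - M
        denoised = double + D
        for b in range(B):
            tree = cKDTree(p_tilde[b])
            _, nb = tree.query(batch[b], k=k_rep)
            nb = nb.reshape(n, k_rep)
            diffs = denoised[b][:, None, :] - p_tilde[b][nb]  # (n, k_rep, 3)
            d2 = np.sum(diffs * diffs, axis=-1)
            jstar = d2.argmax(axis=1)
            rows = np.arange(n)
            l_rep += float(d2[rows, jstar].mean())
            dD[b] += gamma * 2.0 * diffs[rows, jstar] / (n * B)
        l_rep /= B
    total = l_mse + gamma * l_rep
    return D, cache, l_mse, l_rep, total, dD


def train(dataset: list, config: TrainConfig):
    """Train the denoiser on noisy clouds only.

    Parameters
    ----------
    dataset : list of PointCloud
        The observed noisy clouds, in normalized units. No clean reference is
        accepted anywhere in the loop -- the scheme is unsupervised by
        construction.

    Returns
    -------
    (params, TrainHistory)
    """
    if not dataset:
        raise ValueError("empty dataset")
    for i, c in enumerate(dataset):
        r = np.linalg.norm(c.points, axis=1).max()
        if r > 2.0:
            raise ValueError(
                f"cloud {i} has max radius {r:.3g}; training expects clouds in "
                "normalized units (run normalize() first)"
            )
    params = init_model(config.model)
    state = _adam_init(params)
    history = TrainHistory()
    dropout_rng = np.random.default_rng(_derived_seed(config.seed, 0xD0))
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config)
        batches = make_batches(dataset, config, epoch)
        e_mse, e_rep, e_tot = [], [], []
        for bi, batch in enumerate(batches):
            pair_seed = _derived_seed(config.seed, epoch, bi, 0xE5)
            _, cache, l_mse, l_rep, total, dD = _batch_loss_and_grad(
                params, config, batch, pair_seed, dropout_rng
            )
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {bi}: "
                    f"l_mse={l_mse}, l_rep={l_rep}"
                )
            grads = backward_batch(params, config.model, cache, dD)
            _adam_step(params, grads, state, lr, config.model.weight_decay)
            e_mse.append(l_mse)
            e_rep.append(l_rep)
            e_tot.append(total)
        history.append(epoch, lr, float(np.mean(e_mse)), float(np.mean(e_rep)),
                       float(np.mean(e_tot)))
    return params, history


def denoise(
    params,
    config: TrainConfig,
    noisy: PointCloud,
    mode: str = "double",
    realizations: int = 1,
    seed: int = 0,
    predict_fn=None,
) -> PointCloud:
    """Apply the trained displacement model to a noisy cloud.

    ``double`` (default) mirrors the training input distribution: for each of
    ``realizations`` independent draws, inject a fresh M, predict the doubled
    displacement on the double-noisy view, form the estimate Pdot' + dbar',
    and average the estimates per point. ``direct_half`` feeds the noisy cloud
    itself and applies half the predicted displacement (the doubling identity
    in reverse).

    ``predict_fn(points, injected) -> (n, 3)`` optionally replaces the network
    evaluation; intended for analysis with oracle displacement fields.
    """
    if realizations < 1:
        raise ValueError("realizations must be >= 1")
    if mode not in ("double", "direct_half"):
        raise ValueError(f"unknown mode {mode!r}")
    pts = noisy.points

    def _predict(points, injected):
        if predict_fn is not None:
            return np.asarray(predict_fn(points, injected), dtype=np.float64)
        return predict_displacements(params, config.model, points).vectors

    if mode == "direct_half":
        vec = _predict(pts, None)
        out = pts + vec / 2.0
    else:
        acc = np.zeros_like(pts)
        for r in range(realizations):
            M = noise_draw(config.noise, noisy.n, seed=_derived_seed(seed, r))
            dbl = pts + M
            vec = _predict(dbl, M)
            acc += dbl + vec
        out = acc / realizations
    return PointCloud(points=out, frame="raw", norm=noisy.norm, attrs=dict(noisy.attrs))


def save_checkpoint(path, params: dict, config: TrainConfig, history: TrainHistory | None = None):
    """Serialize parameters + full configuration (and history) to one .npz file."""
    arrays = {"__format_version__": np.array([1])}
    for key in ("enc_W", "enc_b", "dec_W", "dec_b"):
        for i, a in enumerate(params[key]):
            arrays[f"{key}_{i}"] = a
    meta = {"config": config.to_dict()}
    if history is not None:
        meta["history"] = history.records
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; returns (params, TrainConfig, TrainHistory)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: [] for k in ("enc_W", "enc_b", "dec_W", "dec_b")}
        for key in params:
            i = 0
            while f"{key}_{i}" in data:
                params[key].append(np.asarray(data[f"{key}_{i}"], dtype=np.float32))
                i += 1
    config = TrainConfig.from_dict(meta["config"])
    history = TrainHistory(records=meta.get("history", []))
    return params, config, history
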