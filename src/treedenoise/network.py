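"""Per-point displacement prediction network, implemented in numpy.

Architecture: a k-NN graph convolution lifts each point to edge features
(neighbor - point relative vectors by default), a shared linear + ReLU layer
followed by max-pooling over the neighborhood produces per-point local
features, further shared (pointwise) linear + ReLU layers deepen them, a
global max-pool over points yields a cloud descriptor, and an MLP head
consuming [per-point feature, global descriptor] emits a 3-vector displacement
per point. The residual convention is that the output is an additive
displacement: denoised = points + vectors.

Both the forward pass and the analytic backward pass (used by the trainer)
live here; everything is float32 and fully deterministic given the
configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ModelConfig",
    "DisplacementField",
    "knn_graph",
    "init_model",
    "extract_features",
    "predict_displacements",
    "forward_batch",
    "backward_batch",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the displacement network.

    ``encoder_widths`` starts at 3 (point dimension) and lists the feature
    widths of the shared encoder layers; ``decoder_widths`` lists the MLP head
    widths and must end at 3 (a displacement vector). ``edge_features``
    selects the graph-convolution lift: ``relative`` uses neighbor - point
    only (keeps the displacement field translation-invariant, hence the
    denoiser translation-covariant); ``dgcnn`` concatenates the absolute point
    coordinates as well.
    """

    k_feat: int = 16
    encoder_widths: tuple = (3, 256, 512, 1024, 2048)
    decoder_widths: tuple = (1024, 512, 256, 3)
    dropout: float = 0.1
    weight_decay: float = 1e-4
    edge_features: str = "relative"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "encoder_widths", tuple(int(w) for w in self.encoder_widths))
        object.__setattr__(self, "decoder_widths", tuple(int(w) for w in self.decoder_widths))
        if self.encoder_widths[0] != 3:
            raise ValueError("encoder_widths must begin with 3")
        if self.decoder_widths[-1] != 3:
            raise ValueError("decoder_widths must end with 3")
        if self.k_feat < 1:
            raise ValueError("k_feat must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.edge_features not in ("relative", "dgcnn"):
            raise ValueError(f"unknown edge_features {self.edge_features!r}")

    @property
    def edge_dim(self) -> int:
        return 3 if self.edge_features == "relative" else 6

    def to_dict(self) -> dict:
        return {
            "k_feat": self.k_feat,
            "encoder_widths": list(self.encoder_widths),
            "decoder_widths": list(self.decoder_widths),
            "dropout": self.dropout,
            "weight_decay": self.weight_decay,
            "edge_features": self.edge_features,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass(frozen=True)
class DisplacementField:
    """Per-point displacement vectors aligned index-wise to an input cloud."""

    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vectors must be (n, 3), got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("non-finite displacement")
        object.__setattr__(self, "vectors", v)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


def knn_graph(points: np.ndarray, k_feat: int) -> np.ndarray:
    """Indices of each point's k nearest *other* points, shape (n, k_feat)."""
    pts = np.asarray(points, dtype=np.float64)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("knn_graph needs at least 2 points")
    if k_feat >= n:
        raise ValueError(f"k_feat={k_feat} must be < n={n}")
    tree = cKDTree(pts)
    # query k+1 and drop the self column
    _, idx = tree.query(pts, k=k_feat + 1)
    out = np.empty((n, k_feat), dtype=np.intp)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k_feat]
        out[i] = row
    return out


def init_model(config: ModelConfig) -> dict:
    """He-initialized parameters, deterministic given ``config.seed``.

    The final head layer starts near zero so the initial displacement field is
    small (the denoiser starts close to the identity).
    """
    rng = np.random.default_rng(config.seed)

    def he(fan_in, fan_out, scale=None):
        s = np.sqrt(2.0 / fan_in) if scale is None else scale
        return rng.normal(0.0, s, size=(fan_in, fan_out)).astype(np.float32)

    enc_W, enc_b = [], []
    widths = config.encoder_widths
    enc_W.append(he(config.edge_dim, widths[1]))
    enc_b.append(np.zeros(widths[1], dtype=np.float32))
    for w_in, w_out in zip(widths[1:-1], widths[2:]):
        enc_W.append(he(w_in, w_out))
        enc_b.append(np.zeros(w_out, dtype=np.float32))

    dec_W, dec_b = [], []
    d_in = 2 * widths[-1]  # [per-point feature, global descriptor]
    for i, w_out in enumerate(config.decoder_widths):
        last = i == len(config.decoder_widths) - 1
        dec_W.append(he(d_in, w_out, scale=1e-3 if last else None))
        dec_b.append(np.zeros(w_out, dtype=np.float32))
        d_in = w_out
    return {"enc_W": enc_W, "enc_b": enc_b, "dec_W": dec_W, "dec_b": dec_b}


def _edge_tensor(X: np.ndarray, idx: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Edge features per (sample, point, neighbor): (B, n, k, edge_dim)."""
    B, n, _ = X.shape
    # gather neighbors: for each b, nbr[b, i, j] = X[b, idx[b, i, j]]
    nbr = X[np.arange(B)[:, None, None], idx]  # (B, n, k, 3)
    rel = nbr - X[:, :, None, :]
    if config.edge_features == "relative":
        return rel
    ctr = np.broadcast_to(X[:, :, None, :], rel.shape)
    return np.concatenate([rel, ctr], axis=-1)


def forward_batch(
    params: dict,
    config: ModelConfig,
    X: np.ndarray,
    idx: np.ndarray,
    *,
    training: bool = False,
    dropout_rng: np.random.Generator | None = None,
    want_cache: bool = False,
):
    """Forward pass on a batch of point sets.

    Parameters
    ----------
    X : (B, n, 3) float array
    idx : (B, n, k_feat) neighbor indices from :func:`knn_graph` per sample.

    Returns ``(D, cache)`` where ``D`` is the (B, n, 3) displacement field and
    ``cache`` holds intermediates for :func:`backward_batch` (``None`` unless
    requested).
    """
    X = np.asarray(X, dtype=np.float32)
    B, n, _ = X.shape
    cache = {"X": X, "idx": idx} if want_cache else None

    E = _edge_tensor(X, idx, config).astype(np.float32)  # (B,n,k,e)
    Z0 = E @ params["enc_W"][0] + params["enc_b"][0]  # (B,n,k,w1)
    mask0 = Z0 > 0
    A0 = np.where(mask0, Z0, 0.0)
    arg0 = A0.argmax(axis=2)  # (B,n,w1)
    F = np.take_along_axis(A0, arg0[:, :, None, :], axis=2)[:, :, 0, :]
    if want_cache:
        cache.update(E=E, mask0=mask0, arg0=arg0)

    enc_inputs, enc_masks = [], []
    for W, b in zip(params["enc_W"][1:], params["enc_b"][1:]):
        enc_inputs.append(F)
        Z = F @ W + b
        m = Z > 0
        F = np.where(m, Z, 0.0)
        enc_masks.append(m)
    if want_cache:
        cache.update(enc_inputs=enc_inputs, enc_masks=enc_masks)

    argg = F.argmax(axis=1)  # (B, wE)
    g = np.take_along_axis(F, argg[:, None, :], axis=1)[:, 0, :]  # (B, wE)
    H = np.concatenate([F, np.broadcast_to(g[:, None, :], F.shape)], axis=-1)
    if want_cache:
        cache.update(argg=argg)

    dec_inputs, dec_masks, drop_masks = [], [], []
    n_dec = len(params["dec_W"])
    for li, (W, b) in enumerate(zip(params["dec_W"], params["dec_b"])):
        dec_inputs.append(H)
        Z = H @ W + b
        if li < n_dec - 1:
            m = Z > 0
            H = np.where(m, Z, 0.0)
            dec_masks.append(m)
            if training and config.dropout > 0:
                keep = 1.0 - config.dropout
                dm = (dropout_rng.random(H.shape) < keep).astype(np.float32) / keep
                H = H * dm
                drop_masks.append(dm)
            else:
                drop_masks.append(None)
        else:
            H = Z
    if want_cache:
        cache.update(dec_inputs=dec_inputs, dec_masks=dec_masks, drop_masks=drop_masks)
    return H, cache


def backward_batch(params: dict, config: ModelConfig, cache: dict, dD: np.ndarray) -> dict:
    """Analytic gradients of the scalar loss w.r.t. every parameter.

    ``dD`` is the loss gradient w.r.t. the (B, n, 3) displacement output.
    Returns a dict with the same structure as ``params``.
    """
    dD = np.asarray(dD, dtype=np.float32)
    grads = {
        "enc_W": [None] * len(params["enc_W"]),
        "enc_b": [None] * len(params["enc_b"]),
        "dec_W": [None] * len(params["dec_W"]),
        "dec_b": [None] * len(params["dec_b"]),
    }

    # ---- decoder (reverse) ----
    dH = dD
    n_dec = len(params["dec_W"])
    for li in range(n_dec - 1, -1, -1):
        Hin = cache["dec_inputs"][li]
        if li < n_dec - 1:
            dm = cache["drop_masks"][li]
            if dm is not None:
                dH = dH * dm
            dH = np.where(cache["dec_masks"][li], dH, 0.0)
        w_in = Hin.shape[-1]
        w_out = dH.shape[-1]
        grads["dec_W"][li] = Hin.reshape(-1, w_in).T @ dH.reshape(-1, w_out)
        grads["dec_b"][li] = dH.reshape(-1, w_out).sum(axis=0)
        dH = dH @ params["dec_W"][li].T

    # split [per-point feature, global descriptor]
    wE = dH.shape[-1] // 2
    dF = dH[..., :wE].copy()
    dg = dH[..., wE:].sum(axis=1)  # (B, wE)
    argg = cache["argg"]
    np.add.at(dF, (np.arange(dF.shape[0])[:, None], argg, np.arange(wE)[None, :]), dg)

    # ---- pointwise encoder layers (reverse) ----
    for li in range(len(params["enc_W"]) - 1, 0, -1):
        dZ = np.where(cache["enc_masks"][li - 1], dF, 0.0)
        Fin = cache["enc_inputs"][li - 1]
        w_in = Fin.shape[-1]
        w_out = dZ.shape[-1]
        grads["enc_W"][li] = Fin.reshape(-1, w_in).T @ dZ.reshape(-1, w_out)
        grads["enc_b"][li] = dZ.reshape(-1, w_out).sum(axis=0)
        dF = dZ @ params["enc_W"][li].T

    # ---- edge convolution ----
    # route dF through the neighborhood max-pool to the argmax edge slot
    B, n, w1 = dF.shape
    k = cache["idx"].shape[-1]
    dA0 = np.zeros((B, n, k, w1), dtype=np.float32)
    np.put_along_axis(dA0, cache["arg0"][:, :, None, :], dF[:, :, None, :], axis=2)
    dZ0 = np.where(cache["mask0"], dA0, 0.0)
    E = cache["E"]
    e_dim = E.shape[-1]
    grads["enc_W"][0] = E.reshape(-1, e_dim).T @ dZ0.reshape(-1, w1)
    grads["enc_b"][0] = dZ0.reshape(-1, w1).sum(axis=0)
    return grads


def extract_features(points: np.ndarray, config: ModelConfig, params: dict):
    """Per-point encoder features and the global max-pooled descriptor.

    Returns ``(F, g)`` with ``F`` of shape (n, encoder_widths[-1]) and ``g``
    of shape (encoder_widths[-1],).
    """
    pts = np.asarray(points, dtype=np.float64)
    idx = knn_graph(pts, config.k_feat)
    X = pts[None].astype(np.float32)
    E = _edge_tensor(X, idx[None], config).astype(np.float32)
    A = np.maximum(E @ params["enc_W"][0] + params["enc_b"][0], 0.0)
    F = A.max(axis=2)
    for W, b in zip(params["enc_W"][1:], params["enc_b"][1:]):
        F = np.maximum(F @ W + b, 0.0)
    if not np.isfinite(F).all():
        raise FloatingPointError("non-finite encoder activations")
    return F[0], F[0].max(axis=0)


def predict_displacements(params: dict, config: ModelConfig, points: np.ndarray) -> DisplacementField:
    """Evaluate the network on one cloud (dropout off, deterministic)."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] <= config.k_feat:
        raise ValueError("need more points than k_feat")
    idx = knn_graph(pts, config.k_feat)
    D, _ = forward_batch(params, config, pts[None], idx[None], training=False)
    if not np.isfinite(D).all():
        raise FloatingPointError("non-finite displacement output")
    return DisplacementField(vectors=D[0].astype(np.float64))
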