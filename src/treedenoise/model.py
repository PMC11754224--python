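"""High-level model/results interface over the training loop.

``DisplacementDenoiser`` is constructed from the observed noisy clouds (no
clean references exist anywhere in the workflow); ``fit()`` runs the
unsupervised training and returns ``DenoiserResults`` carrying the learned
parameters, the loss history, and denoising/evaluation conveniences. Raw-frame
inputs are normalized internally and outputs are mapped back to the original
frame.
"""

from __future__ import annotations

import numpy as np

from .cloud import PointCloud, normalize
from .trainer import (
    TrainConfig,
    TrainHistory,
    denoise,
    load_checkpoint,
    save_checkpoint,
    train,
)

__all__ = ["DisplacementDenoiser", "DenoiserResults"]


def _to_training_frame(cloud: PointCloud) -> PointCloud:
    """Normalize raw clouds; pass through clouds already in normalized units."""
    if cloud.frame == "normalized":
        return cloud
    r = float(np.linalg.norm(cloud.points - cloud.points.mean(axis=0), axis=1).max())
    if r <= 1.5:
        # already unit-scale (e.g. a noisy view of a normalized cloud)
        return cloud
    return normalize(cloud)


class DisplacementDenoiser:
    """Unsupervised displacement-field denoiser for LiDAR point clouds.

    Parameters
    ----------
    clouds : list of PointCloud
        Observed noisy clouds. Raw-frame clouds are unit-sphere normalized
        before training so the configured noise level applies.
    config : TrainConfig, optional
        Defaults to the full-scale recipe; ``TrainConfig.desk()`` gives the
        CPU-scale preset.
    """

    def __init__(self, clouds, config: TrainConfig | None = None):
        if not clouds:
            raise ValueError("need at least one noisy cloud")
        self.config = config if config is not None else TrainConfig()
        self.clouds = [_to_training_frame(c) for c in clouds]

    @classmethod
    def from_files(cls, paths, config: TrainConfig | None = None):
        from .io import read_point_cloud

        return cls([read_point_cloud(p) for p in paths], config=config)

    def fit(self) -> "DenoiserResults":
        """Run the unsupervised training loop; fully reproducible from the
        configuration seed."""
        params, history = train(self.clouds, self.config)
        return DenoiserResults(params=params, config=self.config, history=history)


class DenoiserResults:
    """Fitted denoiser: learned parameters plus training diagnostics."""

    def __init__(self, params: dict, config: TrainConfig, history: TrainHistory):
        self.params = params
        self.config = config
        self.history = history

    # -- inference ---------------------------------------------------------
    def denoise(
        self,
        noisy: PointCloud,
        mode: str = "double",
        realizations: int = 1,
        seed: int = 0,
    ) -> PointCloud:
        """Denoise one cloud, returning it in the frame it came in."""
        was_raw_meters = (
            noisy.frame == "raw"
            and float(np.linalg.norm(noisy.points - noisy.points.mean(0), axis=1).max()) > 1.5
        )
        work = normalize(noisy) if was_raw_meters else noisy
        out = denoise(self.params, self.config, work, mode=mode,
                      realizations=realizations, seed=seed)
        if was_raw_meters:
            rec = work.norm
            out = PointCloud(points=out.points * rec.scale + rec.centroid,
                             frame="raw", attrs=dict(out.attrs))
        return out

    # -- diagnostics -------------------------------------------------------
    @property
    def final_loss(self) -> float:
        return self.history.records[-1]["total"]

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        cfg = self.config
        first = self.history.records[0]
        last = self.history.records[-1]
        n_params = sum(
            int(np.prod(a.shape))
            for key in ("enc_W", "enc_b", "dec_W", "dec_b")
            for a in self.params[key]
        )
        lines = [
            "Displacement denoiser fit",
            "=" * 54,
            f"{'epochs':<28}{cfg.epochs}",
            f"{'batch size':<28}{cfg.batch_size}",
            f"{'patch points':<28}{cfg.patch_points}",
            f"{'noise':<28}{cfg.noise.family}, sigma={cfg.noise.sigma}",
            f"{'encoder widths':<28}{'-'.join(map(str, cfg.model.encoder_widths))}",
            f"{'decoder widths':<28}{'-'.join(map(str, cfg.model.decoder_widths))}",
            f"{'k_feat / k_rep':<28}{cfg.model.k_feat} / {cfg.loss.k_rep}",
            f"{'gamma (repulsion)':<28}{cfg.loss.gamma}",
            f"{'lr (cosine)':<28}{cfg.base_lr} -> {cfg.eta_min}",
            f"{'parameters':<28}{n_params}",
            "-" * 54,
            f"{'first-epoch loss':<28}{first['total']:.6g}"
            f"  (mse {first['l_mse']:.6g}, rep {first['l_rep']:.6g})",
            f"{'final-epoch loss':<28}{last['total']:.6g}"
            f"  (mse {last['l_mse']:.6g}, rep {last['l_rep']:.6g})",
            "=" * 54,
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        save_checkpoint(path, self.params, self.config, self.history)

    @classmethod
    def load(cls, path) -> "DenoiserResults":
        params, config, history = load_checkpoint(path)
        return cls(params=params, config=config, history=history)
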