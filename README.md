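# treedenoise

Unsupervised denoising of LiDAR point clouds for individual-tree extraction.

Airborne and UAV LiDAR surveys of forest plots produce point clouds
contaminated by sensor noise and sparse outliers, which degrades single-tree
segmentation and every downstream inventory quantity (tree height, crown
width, diameter at breast height). Supervised denoisers need clean reference
clouds that field campaigns cannot provide. This package trains a per-point
displacement network on **noisy clouds alone** using a doubled-noise
construction, and ships the matching evaluation metrics, classical baseline
filters (SOR/ROR), and a synthetic forest fixture generator so the whole
pipeline is testable without survey data.

## Method

Let P be the unobserved clean cloud and Ṗ = P + N the observed noisy cloud.
Inject a second, independent noise draw M with the same distribution as N to
form the double-noisy cloud Ṗ′ = Ṗ + M, and record the known displacement
ḋ = Ṗ − Ṗ′ = −M. Because N and M are i.i.d., conditioning on Ṗ′ gives
E(M | Ṗ′) = E(N | Ṗ′), from which the displacement d̄′ that maps Ṗ′ back
to the clean surface satisfies

    d̄′ = 2 d̄,

twice the single-noise displacement. The network f_θ therefore regresses its
per-point prediction d̄′ᵢ onto the observable target 2ḋᵢ:

    L = mean‖d̄′ᵢ − 2ḋᵢ‖² + γ · mean max_{p̃ⱼ ∈ P̃ᵢ} ‖(ṗ′ᵢ + d̄′ᵢ) − p̃ⱼ‖²,

where P̃ = {ṗ′ᵢ + 2ḋᵢ} is the pseudo-clean cloud, P̃ᵢ its k-NN
neighborhood around ṗᵢ, and γ = 5·10⁻⁴. No clean coordinates appear
anywhere in the objective.

The network builds a k-NN graph (k = 16), lifts each edge to relative
coordinates, applies a shared linear+ReLU layer with neighborhood max-pooling
(graph convolution), deepens features with shared pointwise layers
(3-256-512-1024-2048 at full scale), max-pools a global descriptor, and an
MLP head over [per-point feature, global descriptor] predicts an additive
displacement per point: denoised = points + d̄′. Training uses Adam with
weight decay and a cosine-annealed learning rate (0.001 → 1e-5, 200 epochs,
batch 128 at full scale).

At inference, `double` mode mirrors training (inject fresh M, predict,
average over R realizations); `direct_half` mode feeds the noisy cloud and
applies half the predicted displacement.

## Worked example

Train on synthetic noisy spheres and denoise one of them (the desk preset:
50 epochs, batch 8, 3-64-128-256 encoder — a few minutes on one CPU):

```python
import numpy as np
from treedenoise import (DisplacementDenoiser, PointCloud, NoiseSpec,
                         TrainConfig, evaluate, generate_primitive)
from treedenoise.noise import noise_draw

clouds = []
for i in range(32):
    clean = generate_primitive("sphere", 2048, seed=1017 + i)
    M = noise_draw(NoiseSpec(sigma=0.02), 2048, seed=2031 + i)
    clouds.append(PointCloud(clean.points + M))

model = DisplacementDenoiser(clouds, config=TrainConfig.desk(sigma=0.02, seed=1))
res = model.fit()
print(res.summary())
out = res.denoise(clouds[0], mode="double", realizations=8, seed=7)

msd = lambda p: np.mean((np.linalg.norm(p, axis=1) - 1.0) ** 2)
print(f"msd to surface: noisy {msd(clouds[0].points):.2e} "
      f"-> denoised {msd(out.points):.2e}")
```

Output:

```
Displacement denoiser fit
======================================================
epochs                      50
batch size                  8
patch points                2048
noise                       gaussian, sigma=0.02
encoder widths              3-64-128-256
decoder widths              128-64-3
k_feat / k_rep              16 / 4
gamma (repulsion)           0.0005
lr (cosine)                 0.001 -> 1e-05
parameters                  115715
------------------------------------------------------
first-epoch loss            0.00488045  (mse 0.00487554, rep 0.00980456)
final-epoch loss            0.00443863  (mse 0.00443399, rep 0.00928058)
======================================================
msd to surface: noisy 3.92e-04 -> denoised 2.01e-04
```

The loss falls as the network learns the displacement field, and the mean
squared distance of points to the true sphere surface roughly halves after
denoising — noise normal to the surface is removed, while displacement along
the surface (which no surface-based criterion can detect) remains.

The same pipeline is available from the shell:

```sh
treedenoise simulate --shape sphere --n 2048 --seed 1 -o clean.ply
treedenoise add-noise -i clean.ply -o noisy.ply --sigma 0.02 --seed 2
treedenoise train -i noisy.ply -o ckpt.npz --preset desk --seed 3
treedenoise denoise -i noisy.ply -o out.ply --checkpoint ckpt.npz --realizations 8
treedenoise evaluate --ref clean.ply --est out.ply --noisy noisy.ply
```

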