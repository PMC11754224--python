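# Methods

## The doubled-noise training scheme

The denoiser assumes additive, zero-mean, i.i.d. sensor noise: the observed
cloud is Ṗ = P + N with P the unobservable clean geometry. Training injects
a second draw M from the same family and level as N, forming Ṗ′ = Ṗ + M and
the known displacement ḋ = −M. Under the i.i.d. assumption
E(M | Ṗ′) = E(N | Ṗ′), so the conditional-expectation displacement from the
double-noisy cloud back to the clean surface equals twice the single-noise
displacement (d̄′ = 2d̄), making 2ḋ a valid regression target built entirely
from observables. The scheme therefore stands or falls with two assumptions:

- **noise additivity and exchangeability of N and M** — the user must supply
  the family/level of M matching the acquisition noise (on real data N is
  unobservable; the default is Gaussian, sigma 0.1 in normalized units);
- **independence of M from N** — guaranteed here by deriving M's stream from
  the pair seed alone, never from whatever produced the data.

A fresh M is drawn every epoch rather than frozen per sample: the
expectation identity holds over the distribution of M, and resampling
prevents the network from memorizing one realization.

## Loss

`total = l_mse + gamma * l_rep` with gamma = 5e-4.

- `l_mse`: mean over points of ‖d̄′ᵢ − 2ḋᵢ‖². The mean (not sum) reduction
  keeps gamma's scale independent of batch and patch size.
- `l_rep`: for each point, the pseudo-clean cloud P̃ = Ṗ − M is queried at
  the base point ṗᵢ for its k_rep = 4 nearest members, and the loss is the
  mean of the per-point **maximum** squared distance from the denoised
  position to that neighborhood. As printed in its source lineage the term is
  called a repulsion loss although it penalizes a maximum distance (an
  attraction toward the pseudo-clean neighborhood); it is implemented exactly
  as defined and its weight is small. Neighborhoods are recomputed per batch
  from the current pair, never cached across optimizer steps.
- The pseudo-clean cloud is computed in the algebraically reduced form
  `base − injected`, which makes the identity exact in floating point; the
  unreduced form `double + 2·d_dot` agrees to rounding.

## Network

Per-point displacement prediction with three symmetry contracts: permutation
equivariance, translation covariance of the denoised output, and an exact
identity when the head is zero (the residual convention: the network emits
displacements *added* to the input, never absolute positions).

- **Edge features.** The k-NN graph convolution lifts each edge to the
  relative vector (neighbor − point) by default. The common alternative that
  concatenates the absolute point coordinates is available
  (`edge_features="dgcnn"`) but breaks translation covariance — a property we
  consider non-negotiable for georeferenced data, where the same stand
  geometry can appear at any offset. With relative-only features the
  displacement field is translation-invariant, hence denoised = points +
  field translates with its input.
- **Encoder.** One shared linear+ReLU on edge features, max-pooled over the
  k = 16 neighbors, then shared pointwise linear+ReLU layers through widths
  3-256-512-1024-2048 (full scale). Max-pooling over points yields the
  global descriptor; the head consumes [per-point feature, global
  descriptor] through an MLP mirroring the encoder (1024-512-256-3).
- **Initialization.** He-normal everywhere except the final head layer
  (std 1e-3), so training starts near the identity denoiser.
- **Regularization.** Dropout 0.1 on decoder hidden layers (training only)
  and L2 weight decay 1e-4 on weight matrices via the Adam update.
- Implementation is numpy throughout — analytic forward/backward passes in
  float32 with an in-package Adam — which makes every run bit-reproducible
  from the seed on any machine, with no framework nondeterminism.

Subgradient note: ReLU and both max-pools are non-smooth; the backward pass
routes gradients to the argmax slot (lowest index on ties). Zero-initialized
biases leave dead units exactly at the ReLU kink, where finite differences
and the subgradient legitimately disagree — the gradient test jitters
parameters away from that set.

## Training

Adam (beta 0.9/0.999), base lr 0.001 cosine-annealed to 1e-5:
`lr(e) = eta_min + (base_lr − eta_min)(1 + cos(pi·e/epochs))/2`. Full scale
runs 200 epochs with batches of 128 samples; a "sample" is a fixed-size
point set (default 2048 points) subsampled per epoch from one source cloud,
since batched tensors need equal sizes. Training accepts only noisy clouds —
the API has no slot for a clean reference, which enforces the unsupervised
contract structurally. No early stopping (fixed epoch budget).

## Inference

Two protocols are shipped because the test-time treatment is a genuine
design choice:

- `double` (default): inject a fresh M (the training noise spec), predict on
  Ṗ′, output Ṗ′ + d̄′, and average over R realizations. This matches the
  input distribution the network was trained on; averaging removes the
  injected-noise contribution at the Monte-Carlo rate 1/sqrt(R) (verified by
  an oracle-model test). R = 8 is used in the worked example and the
  acceptance run as a good cost/variance point.
- `direct_half`: feed the noisy cloud itself and apply d̄′/2 (the doubling
  identity in reverse). Cheaper, but the network sees a single-noise input
  it was not trained on.

## Evaluation metrics

- **MSE**: mean squared Euclidean point distance over corresponding pairs
  (3-D vector residual, not per-coordinate), with `paired` (index-aligned)
  or `nearest` (NN-matched) correspondence.
- **SNR (dB)**: 10·log10(Ps/Pn), Ps = mean squared point norm of the
  reference in its stored frame, Pn = MSE. Because Ps depends on the
  coordinate frame (georeferenced coordinates give huge Ps), the frame is
  recorded in every report.
- **One-way Hausdorff**: max-min Euclidean distance (scipy's implementation;
  tests verify it against an O(n²) double loop). A symmetric variant is
  exposed separately.
- **3-D SSIM**: for each correspondence pair, each cloud is queried at its
  own point for a k = 16 neighborhood; the local signal is the sorted vector
  of neighbor distances to the neighborhood centroid (rotation- and
  translation-invariant, no voxelization), and the standard SSIM ratio with
  C1 = (0.01·L)², C2 = (0.03·L)² (L = reference bounding-box diagonal) is
  averaged over pairs. Querying each cloud at its *own* corresponding point
  (not both at the reference point) is what makes the score exactly 1 under
  a rigid translation of the estimate.

## Synthetic fixtures

The generator emulates segmented single-tree clouds at desk scale: trunk
points on a cylinder surface, crown points on an ellipsoid surface, plots of
trees placed with minimum spacing, and analytic primitives (unit sphere /
plane / cylinder) for recovery tests. Surfaces (not volumes) are sampled
because LiDAR returns come from surfaces, and because distance-to-surface is
then analytic. What the fixtures do **not** emulate: occlusion and beam
geometry, multi-return structure, anisotropic range noise, vegetation
penetration, and density variation with canopy depth. Passing the recovery
test therefore demonstrates that the training scheme removes additive
isotropic noise from smooth surfaces — it does not certify performance on
real forest scans, whose noise violates the i.i.d. assumption to an unknown
degree.

## Desk-scale study conditions

CPU-scale runs (tests and the acceptance script) use: 32 unit spheres of
2048 points, independently corrupted at sigma 0.02; desk preset = 50 epochs,
batch 8, whole 2048-point clouds as samples, encoder 3-64-128-256, decoder
128-64-3, k_feat 16, gamma 5e-4, lr 0.001→1e-5. Whole clouds (rather than
subsampled patches) are used as samples at desk scale because the k-NN
neighborhood scale at training time then matches evaluation time; with 4
batches per epoch this gives 200 optimizer steps, about three minutes on one
CPU. Recovery is measured as mean squared distance to the analytic sphere;
the denoised target is ≤ 60% of the noisy value. Note the paired MSE to the
clean cloud improves only slightly under this test: denoising projects
points toward the surface but cannot recover their tangential positions,
which is invisible to any surface-distance criterion and inherent to the
method class.

## Degenerate inputs and numerical choices

- Normalization (centroid + unit max radius) rejects all-coincident clouds;
  noise levels are interpreted in normalized units (a stated modeling
  choice: the source recipe's 0.01–0.1 intensities are unitless there too).
- LAS output quantizes to a 0.001 m grid (the written coordinate scale);
  PLY is written with double-precision vertices so round trips are exact to
  1e-9; LAZ input is rejected (no decompressor dependency).
- k-NN ties: brute-force paths break ties by lowest index; kd-tree paths
  (scipy) may order exact ties arbitrarily. Random/continuous clouds have no
  ties; grid-like data may see benign neighbor-order differences.
- Non-finite losses abort training with the epoch/batch named; non-finite
  network outputs raise rather than propagate.

## Known limitations

- Noise family/level of M must be supplied; a mismatch with the true
  acquisition noise biases the learned displacements.
- The repulsion term is implemented exactly as specified by its printed
  definition; with gamma = 5e-4 its influence is small, and its "repulsion"
  naming does not match its attractive behavior.
- No multi-GPU or minibatch-parallel training; the numpy implementation
  targets desk-scale experiments, not production-scale plots.
- Outlier contamination (heavy-tailed kicks) is supported by the noise model
  but excluded from the core doubled-noise identity when enabled; classical
  SOR/ROR prefiltering is the recommended treatment for gross outliers.
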