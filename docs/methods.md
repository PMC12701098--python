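# Methods

This document describes the algorithms, models, and numerical choices in
`ailabel3d`, a package for generating tumor segmentation labels on 3D
multi-modal MRI with minimal expert input, and for measuring how well those
labels train a downstream segmentation network.

The pipeline has two stages. Stage one clusters every voxel of a T1/T2
volume pair without any labels, using a small dual-branch 3D CNN trained by
differentiable feature clustering. Stage two converts the cluster map plus a
pair of coarse expert tumor outlines into a final binary "AI-assisted label"
(AI-L) by seeded, cluster-aware region growing. The AI-L can then be used in
place of a voxel-accurate expert label (EL) to train a dual-channel 3D U-Net,
and the evaluation module quantifies the difference.

## 1. Numerical core (`ailabel3d.nn`)

The package ships its own minimal reverse-mode layer library in NumPy rather
than depending on a deep-learning framework. The networks involved are small
and run on a single CPU core, so explicit, auditable backward passes are both
feasible and easy to verify against finite differences and independent
oracles (the test suite does both).

All layers operate on single samples laid out channel-first as `(C, H, W, D)`
float32 arrays; mini-batching is gradient accumulation over samples.

- **Conv3d** — stride 1, odd kernel, "same" zero padding. The forward pass
  is evaluated as one BLAS matrix product per kernel offset against a strided
  slice of the zero-padded input. This avoids materialising an unfolded
  `im2col` column matrix (whose gather cost dominated runtime in profiling)
  while still routing all arithmetic through GEMM. The backward pass is the
  exact adjoint of the same decomposition: per offset, the weight gradient is
  `dY · slice(X)ᵀ` and the input gradient scatters `Wᵀ · dY` back into the
  padded buffer. Weights are Xavier-uniform initialised with fan counts
  `c_in·k³` / `c_out·k³`.
- **ChannelNorm** — per-channel normalisation over the spatial voxels of the
  current sample, with learnable affine (`gamma`, `beta`). Statistics come
  from the sample itself in both training and evaluation mode, so forward
  passes are deterministic functions of the input and independent of batch
  composition. This is the single-sample formulation of batch normalisation
  that differentiable feature clustering uses; it also removes the need for
  running averages.
- **MaxPool2x / UpsampleNearest2x** — 2×2×2 pooling with argmax routing on
  the backward pass, and nearest-neighbour upsampling whose adjoint is a
  block sum. Both are used only by the U-Net.
- **Optimisers** — SGD with optional Nesterov-free momentum, and Adam with
  bias correction.

Gradient correctness is tested layer-by-layer with central finite
differences on fixed smooth functionals, and the convolution forward pass is
tested against `scipy.ndimage.correlate`.

## 2. Unsupervised feature clustering (`ailabel3d.featcluster`)

### Model

Two structurally identical but independently initialised branches process
the T1 and T2 volumes (no weight sharing, so each branch can specialise to
its contrast mechanism). Each branch is `n_blocks = 3` blocks of
3×3×3 convolution (stride 1, same padding) → ReLU → ChannelNorm, except the
last block omits the ReLU so the embedding is not clipped at zero. Each block
carries 30 channels per branch; the branch outputs are concatenated to a
60-channel per-voxel embedding and passed through a final ChannelNorm. The
normalised embedding is the *response map*; a voxel's cluster is the argmax
channel of its response.

### Losses

Training minimises `L = L_sim + μ · L_con` with `μ = 1`:

- **Similarity (self-labelling cross-entropy).** The argmax labels of the
  current forward pass are taken as constant targets and the mean
  cross-entropy between the softmaxed response and those targets is
  minimised. No gradient flows through the argmax. On a constant response
  map this loss equals `log q` exactly (uniform softmax), which the tests
  assert to 1e-12 relative error.
- **Continuity (3-axis L1).** The mean absolute forward difference of the
  response map along the three spatial axes, normalised by the total number
  of (pair, channel) elements. This penalises spatial label fragmentation
  and is what drives cluster merging.

Both losses are computed in the dtype of the response (float32 during
training; float64 inputs retain float64 precision, which the oracle tests
rely on).

### Adaptive cluster merging

There is no explicit merge step. The network starts with `q = 60` possible
clusters; as training sharpens the response map, channels that stop winning
any voxel's argmax simply disappear from the cluster maps. The per-epoch
history records `n_active_clusters`, the number of distinct labels across
the whole cohort's cluster maps. This count is monitored, never controlled:
it cannot exceed `q` and typically collapses by an order of magnitude.

### Training loop

Plain SGD (momentum 0.9) over shuffled mini-batches, with per-sample
augmentation: a flip along the W axis with probability 0.3 and an in-plane
rotation about the depth axis uniform in ±15°, applied identically to both
modalities. Early stopping monitors the training loss (there is no labelled
validation signal in unsupervised training) with a configurable patience.
All randomness derives from one `rng_seed` via `numpy.random.SeedSequence`
spawning, so runs are bit-reproducible.

At full clinical scale the intended settings are batch size 4 and learning
rate 0.001 over a cohort of >100 cases. At the desk scale this repository
targets (a handful of 48×48×16 phantoms on one CPU core), the cohort is two
orders of magnitude smaller, so an epoch provides far fewer parameter
updates. The scaled experiments therefore use batch size 1 (five updates per
epoch on a five-case cohort) and learning rate 0.1 — matching the *update
count and step magnitude* of the full-scale recipe rather than its literal
batch size. These are configuration values, not code changes; the defaults
in `ClusterTrainConfig` remain the full-scale ones.

## 3. Seeded cluster-aware refinement (`ailabel3d.refine`)

Inputs: a cluster map, and two coarse binary expert outlines (one drawn on
each modality). Steps:

1. **Isolate** — the expert outlines are added element-wise; the region is
   `(EL_t1 + EL_t2) > 0`. The cluster map is multiplied by this region:
   cluster values are kept inside it and set to a sentinel (−1) outside.
2. **Seed** — `n_seeds` voxels are sampled from the region without
   replacement, stratified so every cluster label occurring in the region
   receives at least one seed when `n_seeds` permits (mimicking an expert
   clicking once on each visible cluster); remaining seeds are uniform.
3. **Grow** — from each seed, region growing expands over the *full* cluster
   map to the 6-connected component of voxels sharing the seed's cluster
   label. Growth is by label, not intensity, and may extend beyond the
   isolated region.
4. **Filter** — the tumor volume is estimated as the voxel count of the
   combined expert region. Grown masks with volume strictly greater than
   3× the estimate are discarded (boundary inclusive: exactly 3× is kept).
   Duplicate masks (two seeds landing in one component) are kept once.
5. **Compose** — the surviving masks are summed (logical union) into the
   AI-L. By construction the AI-L is a union of whole cluster components.

If no mask survives the filter, the combined expert region itself is
returned and the provenance record flags the fallback. The provenance also
records seeds, per-mask volumes, and retention decisions.

## 4. Downstream 3D U-Net (`ailabel3d.unet3d`)

A standard encoder–decoder with skip connections, taking the two modalities
as a dual-channel input. Each level is one conv block (3×3×3 conv →
ReLU → ChannelNorm); downsampling is 2× max pooling, upsampling is nearest
neighbour followed by concatenation with the skip feature and a conv block.
A 1×1×1 convolution plus sigmoid produces the per-voxel tumor probability.
Widths double per level from `base_width`. Training uses Adam (lr 0.001,
batch 4 by gradient accumulation), Xavier initialisation, soft Dice loss
with an analytic gradient, the same flip/rotation augmentation applied
jointly to inputs and labels, and early stopping on validation loss with
best-weight restoration. `predict` thresholds the probability map; the
thresholded mask is monotonically non-increasing in the threshold.

The training target can be either the EL or the AI-L (`label_source`),
which is what enables the label-quality comparison.

## 5. Evaluation (`ailabel3d.evalx`)

- **Dice / FNR / FPR** with explicit edge-case conventions: Dice of two
  empty masks is 1.0; FNR is 0 when the reference is empty; FPR is 0 when
  the reference covers the volume.
- **Intra-cluster homogeneity** — per-volume z-normalised intensities are
  pooled per (cluster, modality) across cases; the population variance of
  each pool measures heterogeneity, and clusters are ranked by the mean of
  the two modality variances, descending. Tumors, being the most
  heterogeneous tissue, are expected to rank first once clusters align with
  tissues. Labels with fewer than two pooled voxels are flagged undefined
  and excluded from the ranking.
- **Blinded comparison machinery** — for each case, two model outputs are
  presented in randomised order with randomised colour assignment; the
  rater sheet carries no model identifiers. The tally reconstructs per-rater
  counts from the unblinding key and computes the majority verdict, which
  with three raters requires at least two agreeing.

## 6. Synthetic phantom cohort (`ailabel3d.phantom`)

Real clinical cohorts are private, so the package ships a phantom generator
that reproduces the *statistical structure* the pipeline relies on:

- Nested anatomy: background, subcutaneous fat, muscle, a bone cylinder,
  and vessel tubes, each with modality-specific Gaussian intensities whose
  means are separated by ≥2 pooled SDs in at least one modality (the
  clusterability precondition).
- An ellipsoidal tumor at a seed-dependent position inside bone or muscle.
  Tumor voxels get the highest nominal SD *and* a smooth low-frequency
  modulation field (Gaussian-filtered noise scaled to 1.5× the tumor SD),
  making intra-tumor variance strictly the largest — the property the
  homogeneity analysis is meant to recover.
- Simulated expert labels per modality: the true tumor mask eroded or
  dilated by one step (a per-modality bias) plus boundary jitter, emulating
  coarse, slightly inconsistent manual outlines.

Phantom realism is deliberately limited: no bias fields, no partial-volume
blur at tissue borders, no anisotropic voxels, single tumor per case. These
omissions keep the generator analysable; the acceptance experiments test
parameter *recovery*, not clinical realism.

## 7. Problem sizes

Default experiment sizes are chosen for a single CPU core:

- Clustering cohort: 5 cases at 48×48×16, `q = 60` — large enough for the
  cluster-collapse dynamics to show, small enough for minutes-scale runs.
- Reduced clustering runs (homogeneity and label-generation sweeps over
  many seeds): 2 cases at 32×32×12 with `q = 20`.
- U-Net: depth 2, base width 4, 10 cases at small shapes for learnability
  checks.

All sizes are configuration, not constants; the same code paths run at
clinical scale given the compute.
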