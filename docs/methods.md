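# Methods

## Problem and approach

Clinically deployed segmentation pipelines receive inputs they were never
trained on — wrong modality, corrupted preprocessing, artefacts — and
task-model uncertainty alone does not reliably flag them. This package
implements likelihood-based out-of-distribution (OOD) filtering for 3D
volumes: a vector-quantising autoencoder (VQ-VAE, optionally with an
adversarial discriminator) compresses a volume `x ∈ R^{H×W×D}` to a grid of
discrete codebook indices, the grid is flattened to a token sequence
`s = (s_1, …, s_n)` in a fixed raster order, and a causal transformer models

    p(s) = ∏_i p(s_i | s_<i),

so every volume receives an *exact* log-likelihood in nats. A one-sided
threshold on the log-likelihood rejects OOD inputs; reshaping the per-token
conditionals back onto the latent grid and nearest-neighbour upsampling gives
a spatial map of where the model was surprised. Segmentation-uncertainty
baselines (softmax probability, deep ensembles, MC dropout) are provided for
comparison, along with a 14-corruption near-OOD benchmark.

Everything runs on a small tape-based numpy autodiff core (`ltm_ood.nn`)
written for this package: no GPU framework is required, and desk-scale
experiments (32³ volumes, 512-token sequences) train in minutes on one CPU.

## Synthetic phantoms

Clinical head-CT cohorts are not shareable, so all experiments run on seeded
synthetic phantoms that reproduce the gross structure the method exploits:

- zero background (air after clamp-and-rescale preprocessing maps to 0),
- a bright ellipsoidal shell ("skull", default intensity 0.95, thickness 2
  voxels) whose semi-axes are jittered ±15% per seed around
  (0.8, 1.0, 0.8) × half-extent,
- a mid-intensity interior ("brain", default 0.45) with smooth Gaussian
  texture (sd 0.04, smoothing σ = 1 voxel), clamped to [0, 1],
- optional compact bright lesions (default 0.85, mimicking hyperdense
  haemorrhage) strictly inside the brain mask, with voxel-exact masks.

Default grid is 32³ (full-scale 176×208×176 is supported by the same code
but not exercised). What the phantoms deliberately do **not** model: CT
physics (beam hardening, streaks), anatomy (ventricles, folds, asymmetry),
inter-scanner intensity variation, registration error. A green test therefore
establishes that the pipeline's machinery behaves as specified on data with
head-CT-like gross structure — not that clinical performance numbers
transfer.

Because the phantoms are centred and share intensities, the dataset-mean
image is an unusually strong reconstruction baseline; the test that a trained
compressor out-reconstructs it uses a 1-level, K=128 configuration where the
decoder retains enough full-resolution capacity (see "Numerical choices").

## Corruption suite

Fourteen sub-classes: Gaussian noise with sd σ ∈ {0.01, 0.1, 0.2};
background value replaced by b ∈ {0.3, 0.6, 1.0} (exact-zero voxels only,
valid because preprocessing maps background to 0); flips through the three
central planes (masks co-flipped); deletion of a slab of ⌊0.2·extent⌋ axial
slices, centred or abutting the top; mask-based skull-strip; global intensity
scaling by c ∈ {0.1, 0.01}. Noise is *not* clamped back to [0, 1]: clamping
would censor exactly the signal the corruption is meant to add. The noise
parameter is a standard deviation — at these values sd-scaled noise is
subtle at the low end and clearly visible at σ = 0.2, whereas reading them
as variances would make the weakest level destroy the image. Noise seeds are
derived from a hash of (source id, corruption identity) so cohort corruption
is reproducible without bookkeeping.

## VQ compression

Encoder: a 3×3×3 stem, then per level a stride-2 4×4×4 convolution plus a
residual block (ReLU), then a 1×1×1 projection to the n-dimensional latent.
Channel widths double per level from `base_channels` (default 4). Each latent
vector is replaced by its nearest codebook entry in squared L2; ties break to
the lowest index. Gradients cross quantisation by the straight-through
estimator; the codebook itself receives no gradient and is re-estimated by
exponential moving averages (decay γ = 0.99, Laplace smoothing ε = 1e-5):
counts and vector sums are EMA-updated per batch and entries are the
smoothed means.

Decoder: mirror of the encoder with nearest-neighbour ×2 upsampling followed
by a stride-1 convolution in place of transposed convolutions
(resize-convolution: identical receptive behaviour at these scales, no
checkerboard artefacts, and a much simpler exact gradient in the numpy core).
The convolution after the *final* upsample defaults to kernel 1 (a pure
channel mix; the 3×3×3 output convolution still smooths) because a 3×3×3
kernel at full resolution dominates CPU cost; `final_up_kernel=3` buys
sharper reconstructions at roughly twice the step time and is used where
reconstruction fidelity is the point.

Losses (weighted sum; weights in `VQConfig.loss_weights`):

- `mse` — mean squared voxel error;
- `spectral` — mean squared modulus of the difference of the full complex
  DFTs, per voxel. By Parseval this equals the MSE exactly; it is kept as a
  separately computed component so ablation configurations remain expressible,
  and the equality is asserted in tests rather than assumed;
- `perceptual` — feature-space MSE through a pluggable extractor. No
  pretrained network is available offline, so the built-in extractor is a
  *fixed random-weight* conv stack (a synthetic stand-in: random projections
  of local neighbourhoods still penalise structural mismatch differently
  from voxel MSE). Off by default;
- `commitment` — mean squared distance between encoder outputs and their
  assigned entries, weight β = 0.25 (standard VQ-VAE practice);
- `adversarial` — hinge generator loss from a small patch discriminator,
  off by default; when enabled the discriminator trains alternately with the
  usual hinge real/fake objective.

Training: Adam (lr 3e-3 at desk scale; small nets tolerate and need the
higher rate), batch 8. By default quantisation is active from the first step
and the codebook is initialised from encoder latent samples — the plain EMA
recipe. An optional warmup (`warmup_epochs > 0`) first trains the plain
autoencoder and then seeds the codebook with Lloyd k-means centroids of the
warmed-up latents. The tradeoff matters: warmup + k-means gives sharper
reconstructions and fuller code usage, but it centres every code on the
clean-data latent clusters, so dim or rescaled inputs collapse onto a single
well-fitting background code whose constant sequence the autoregressive
model then scores as *highly likely* (the familiar failure of likelihood
models on overly simple inputs). With the default sample-initialised
codebook, rescaled inputs land on rarely-used codes and their likelihood
collapses, which is the behaviour the OOD filter depends on. Use warmup only
when reconstruction fidelity is the goal. The decoder's output convolution
is initialised at 0.1× Kaiming scale so optimisation starts from a near-zero
image rather than a high-variance one.

## Autoregressive likelihood

The code grid is flattened in C order (axis 0 slowest, last axis fastest).
The raster order is part of the model artefact — likelihoods are
order-dependent — so it is fixed, not configurable per call. The sequence
model is a pre-LN decoder-only transformer with exact causal attention,
learned absolute positional embeddings, and vocabulary K+1: a begin-of-
sequence token is prepended so the first position has a well-defined
conditional, and output logits cover only the K real codes so every
conditional normalises over the code vocabulary. Exact attention replaces
linear-attention approximations deliberately: at desk-scale sequence lengths
(≤ 512) the quadratic cost is immaterial and the likelihood is exact.

Package default is 4 layers, 4 heads, width 128; the scaled experiment uses
2 layers, 2 heads, width 64 to fit a single-CPU budget (the separation task
at phantom scale does not need the larger model). Training minimises
next-token cross-entropy with Adam (lr 5e-4 default), seeded shuffling, and
is bitwise deterministic given the seed.

Scores: `total_loglik` is the sum of per-token conditional log-probabilities
(nats). Spatial maps reshape the per-token values back to the latent grid and
nearest-neighbour upsample by an integer factor per axis (16 at full scale,
4 at 32³ with 2 levels).

## Segmentation uncertainty baselines

A small 3D U-Net (instance norm, leaky ReLU, stride-2 down, resize-conv up,
skip concatenation; desk-scale features (8, 16, 32), full-scale preset
(32, 32, 64, 128, 256)) with 2-class softmax output. Dice loss by default;
cross-entropy for the softmax baseline. Optimiser is AMSGrad Adam.

Certainty constructions: softmax baseline = the foreground probability of a
single network; ensembles and MC dropout (p = 0.5, dropout active at
inference, N = 5 passes) average the N foreground probabilities into a mean
class distribution p̄ and use certainty 1 − H(p̄) with H in nats. Entropy is
computed on the *mean* distribution (the mean-then-entropy reading; the
alternative entropy-then-mean is not implemented). The binary prediction is
the majority vote of the N thresholded (0.5) members; lesions are 26-connected
components (configurable to 6); per-lesion confidence is the mean per-voxel
certainty over the component. A predicted component is a true positive when
at least 50% of *its own* voxels overlap ground truth — the predicted
component is the denominator because the quantity scores predictions.

## Evaluation

AUC uses the Mann–Whitney pairwise construction with half-weight ties,
computed via ranks; direction is explicit (`low_is_ood` for log-likelihood,
`high_is_ood` for reconstruction error). The reconstruction-MSE baseline
reports plain MSE and a mean-intensity-normalised variant (flagged undefined
for an all-zero image rather than raising). Threshold policies are either an
absolute log-likelihood cut or a percentile of training scores. The
likelihood-versus-false-positive-count analysis joins per-volume scores with
FP lesion counts and reports Spearman rank correlation (flagged undefined
when either variable is constant).

The scaled experiment trains on 200 clean 32³ phantoms (2-level VQ, K = 32),
scores 20 held-out clean volumes against 20 corrupted volumes per sub-class,
and reports per-class mean (sd) log-likelihood and AUCs for both the
likelihood and the MSE baseline. Expected pattern, mirrored from full-scale
behaviour: background/scaling/skull-strip corruptions separate perfectly;
the subtlest noise (σ = 0.01) is indistinguishable; flips of a near-symmetric
phantom stay near 0.5; deleted-chunk volumes are localised by the spatial
map (lower mean conditional log-probability inside the deleted slab).

## Numerical choices and degenerate inputs

- Quantisation ties break to the lowest codebook index (numpy argmin).
- The module-level `quantize` computes exact per-pair distances; the training
  path uses the expanded-norm GEMM form for speed (equal up to float error;
  the exhaustive oracle is tested against the exact form).
- Loss decomposition: `total` equals the weight-weighted sum of parts to
  1e-6; parts are reported unweighted.
- Non-divisible shapes are zero-padded up to the next multiple of 2^levels
  and cropped after decoding; the pre-padding shape travels with the code
  grid.
- `background_value` matches voxels exactly equal to 0 — valid only under
  the preprocessing convention that background is exactly 0.
- Empty segmentation predictions yield an empty lesion list, not an error;
  `fp_count` on them is 0.
- EMA entries of never-assigned codes stay (up to smoothing) at their
  initialisation, since counts and sums decay proportionally.
- All randomness flows through explicit integer seeds; derived seeds are
  kept below 2^31.

## Known limitations

- Phantom realism is deliberately minimal (see above); absolute likelihood
  values and AUCs on phantoms do not transfer to clinical data.
- The spectral loss as defined is redundant with MSE (Parseval); a magnitude-
  spectrum loss would differ but is not what the pipeline specifies.
- The perceptual extractor is untrained; it is a placeholder interface, not
  a learned perceptual metric.
- The discriminator is a minimal patch classifier; adversarial training is
  functional but not tuned, and is off in all default configurations.
- Sequence models are trained per latent geometry: a model trained at one
  sequence length cannot score another.
- The intensity-scaling / background-value separation depends on rescaled
  inputs mapping to unusual codes; with small training cohorts (≲100
  phantoms) or a k-means-seeded codebook they can instead collapse onto a
  single well-fitting code and score deceptively well. The 200-phantom
  default cohort with the sample-initialised codebook behaves correctly.
- Sampling/generation from the sequence model is out of scope.
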