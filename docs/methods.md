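# Methods

## Coding network

The network is a fixed six-convolution stack (see the README table) taking
140×140×3 RGB patches to a 6-way softmax. Conventions that the published
shape arithmetic forces and that this implementation fixes explicitly:

- **Zero padding everywhere and floor-convention pooling** (partial windows
  discarded). These are the only settings under which the stage sizes
  134 → 128 → 62 → 54 → 25 → 19 → 13 → 4 → 1 are self-consistent; the
  accompanying prose mentions an 8×8 receptive field and only 5×5 pooling,
  which match no consistent stack, so the table is taken as authoritative.
- **Activation**: rectified linear units after every convolution and after
  the full-connection layer (the activation is not stated in the source
  description; ReLU follows the AlexNet-style design the normalization and
  dropout choices come from).
- **Local response normalization** after the activations of the first two
  convolutions, with the classic hyperparameters (window 5, k = 2,
  α = 1e-4, β = 0.75), configurable per layer. Placement after exactly the
  first two convolutions is our reading of "convolutions followed by
  normalization"; it is the conventional position and is exposed as a flag
  on each layer spec.
- **Dropout** (p = 0.5 default) after the full-connection layer only — the
  only hidden fully connected layer before the softmax. Inverted dropout:
  survivors scaled by 1/(1−p) at train time, identity at inference.
- **Initialization**: zero-mean Gaussian with standard deviation
  √(2/fan-in) per layer, seed-controlled; biases zero.
- **Input normalization**: the per-channel mean of the training split is
  subtracted from every image; the mean is stored on the trained network so
  feature extraction and prediction apply it identically.

Training is momentum SGD (defaults: batch 100, momentum 0.9, initial rate
0.01, 45 epochs) on the cross-entropy loss. The published protocol adjusted
the learning rate manually, dividing by 10 when validation error stopped
improving; here that is automated as: divide by `lr_drop_factor` (10) after
`plateau_patience` (5) consecutive epochs without a new best validation
error rate. The exact manual criterion is unknowable; patience is
configurable. Everything — im2col convolution, max-pool argmax scatter, LRN
and its gradient, backprop — is numpy; training is exactly reproducible
given the seed because execution is single-threaded with a fixed reduction
order. Backpropagation is verified against central differences on a small
float64 network in the test suite.

## Feature fusion

The description of the 2048-wide convolutional feature conflicts with the
table (the sixth convolution outputs 1×1×256). The only 2048-element
activation in the network is the flattened final max-pool output
(4×4×128), so **cfr = flattened final max-pool activations**, in row-major
(height, width, channel) order — fixed so serialized features are
byte-reproducible. **ffr** is the 256 full-connection activations taken in
inference mode (dropout off), before the softmax head. Fusion is plain
concatenation, cfr first: 2048 + 256 = 2304 columns.

## Sparse autoencoder

Three layers, logistic sigmoid in both the encoder and decoder. The cost is
the mean squared reconstruction error plus β times the summed Bernoulli KL
divergence between the sparsity target ρ and each hidden unit's mean
activation ρ̂ⱼ. Decisions where the source leaves gaps:

- **Sigmoid activation**: the KL penalty requires hidden activations in
  (0,1), which forces a sigmoidal hidden layer; a sigmoid output layer then
  pairs with inputs min-max scaled per column to [0,1] on the training
  split (the stored scaling is reused at encode time).
- **Untied weights** (separate encoder and decoder matrices): the general
  case; a tied model is the special case W_dec = W_encᵀ.
- **No weight decay by default** (the cost has no decay term); an optional
  coefficient exists for users who want it.
- **Hyperparameters** ρ = 0.05, β = 3, hidden size s₂ = 256 by default
  (matching the ffr scale); none are stated in the source and all are
  configurable. The desk-scale pipeline uses s₂ = 32 against its 96-wide
  fused features.
- **Numerical safety**: ρ̂ⱼ is clipped to [1e-10, 1−1e-10] before the
  logarithms so the cost is finite at extreme initializations; the gradient
  uses the same clipped value.

The analytic gradient includes the KL term's coupling through ρ̂ⱼ (a mean
over samples, so the penalty ties all rows of a batch together); it matches
central-difference gradients to relative error < 1e-6 on randomized small
instances (an acceptance-level property test).

Optimization is full-batch gradient descent with momentum plus a
backtracking guard: a step that would increase J_sparse is rolled back, the
rate halved and momentum reset. This makes the recorded cost history
monotone non-increasing by construction, at the price of occasionally
conservative steps — an acceptable trade for a reduction stage whose inputs
are only a few thousand rows.

## PCA baseline

Centering-only PCA (no variance scaling — the reduction operates on raw
fused features), 1/(m−1) covariance, full SVD. The sign of each component
is fixed (largest-magnitude entry positive) for cross-platform
reproducibility. The retained width k defaults to the SAE hidden size so
the two reduction arms feed the classifier equal-width inputs; a
variance-fraction criterion can be used instead by choosing k externally
from `explained_variance_ratio`.

## Evaluation

Labels are 1-based; prediction is the argmax of the probability row with
ties broken toward the lower class index. The confusion matrix carries
per-class precision (column margins) and recall (row margins); a class that
is never predicted gets precision 0 and is flagged. "Per-class accuracy" in
the comparison table is per-class recall (diagonal over row total). ROC
curves are one-vs-rest on the class's probability column with tied scores
grouped into single threshold steps, anchored at (0,0) and (1,1); AUC is
trapezoidal, which under this tie handling equals the Mann–Whitney rank
statistic (verified to 1e-12 in the tests). Mean AUC is the unweighted
average over classes; class-frequency weighting is available. The softmax
classifier for the reduced arms is scikit-learn's multinomial logistic
regression (lbfgs, mild L2 with C = 10 for conditioning), deterministic for
fixed inputs; the coding-network arm is the network's own softmax head.

## Synthetic data

Each class is a base RGB colour plus an oriented sinusoidal stripe field
(class-specific frequency, 4–19 cycles per image width, and orientation in
30° steps) plus i.i.d. Gaussian noise (σ = 0.05), with a random phase per
image. Frequencies are defined per image width, so the pattern survives the
patch-and-resize step at any scale. This emulates only the *statistical*
structure the pipeline needs — class-distinguishable colour and texture
statistics — and none of the morphology of stained tissue (no nuclei,
staining gradients, magnification artifacts, or annotation noise). Passing
tests therefore demonstrate that the pipeline's machinery works and that
the arms are compared fairly, not that real-data accuracy rankings would
reproduce. The classes are cleanly separable by construction (a logistic
model on eight hand-crafted features already beats twice chance), which is
why desk-scale runs saturate near 100%.

Choices not fixed by the source material:

- **Patches per source image**: never stated; default 10, and 3 in the
  desk-scale pipeline to keep run time in minutes.
- **Split leakage**: whether patches from one source image could straddle
  splits is unstated; here the 7:1:2 split is assigned per *source image*
  (stratified by class, largest-remainder apportionment), so all patches of
  a source share a split. This is the conservative choice.
- **Resizing**: bilinear, which preserves constant patches and keeps values
  in [0,1]; anti-aliasing prefilter when downsampling.
- The k-fold protocol re-splits each fold's remainder 4:1 into
  train/validation (stratified) so every class retains validation samples
  even at small n.

## Problem sizes

The default test and demonstration scale uses the six-class dataset shrunk
by ≈0.23 (source 468×351, patch 219, network input 32×32, ~460 source
images, 3 patches each → ~1,380 patches) and a same-pattern network with
channels (8, 8, 16, 16, 32), fc 64, trained 15 epochs with batch 50 —
chosen so a full three-arm comparison completes in a few minutes on one
CPU while every structural property of the full-size configuration (shape
arithmetic, 2048/256/2304 feature widths) is still exercised exactly at
full size where it is cheap (single forward passes).

## Known limitations

- The full-size network is only ever *forwarded* here, not trained to
  convergence; the published real-data accuracies cannot be checked against
  it because the underlying dataset is private.
- LRN placement, activation choice, SAE hyperparameters and the plateau
  criterion are reasoned reconstructions (documented above), not stated
  facts of the source configuration.
- The SAE optimizer is full-batch; for feature matrices far beyond ~10⁴
  rows a mini-batch variant would be preferable.
- The synthetic generator's clean separability means comparison *margins*
  between arms carry no information at desk scale.
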