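# Methods

## Problem and model

`mrh` learns a local mapping from multi-contrast MR signals to the
intensity of a histological stain.  The unit of learning is a small
in-plane patch: a `k x k x C` block of co-registered signal channels
(k = 3 by default) paired with the corresponding `k x k` patch of the
target stain.  MR signals are ensemble averages over each voxel, so a
voxel's multi-contrast signature — not long-range image context — is
assumed to carry the information about its cellular composition; the
small patch exists mainly to absorb residual registration mismatch
between the modalities, not to provide texture context.

The regressor is a residual convolutional network:

* one input convolution `C -> F` and one `F -> F`, each with a ReLU;
* `n` residual blocks, each `[conv F -> F, ReLU, conv F -> F]` with an
  identity skip connection added to the block output;
* two tail convolutions, `F -> F` with ReLU and `F -> 1`.

All convolutions are 3 x 3 with same zero-padding, so the spatial
extent is preserved and the total convolutional layer count is
`2n + 4` — 64 layers at the default `n = 30`, `F = 64`.  There are no
normalization layers.  The four non-residual layers are split two at
the input and two at the output end; this arrangement is a package
decision (only the count is canonical).

Training minimizes the mean absolute error over batch and patch
voxels with SGD: momentum 0.9, batch 128, initial learning rate 0.1
multiplied by 0.1 every 10 epochs (staircase, i.e. epochs 1–10 run at
0.1), at most 60 epochs, early stopping when the validation loss has
not decreased for 5 consecutive epochs, 1000 randomly held-out
validation patches, and selection of the weights from the epoch with
the lowest validation loss (earliest epoch on ties).  Weights are
initialized as (semi-)orthogonal matrices; the second convolution of
each residual block is additionally scaled by 0.1 at initialization
so that the stack is near-identity at depth.  Without this scaling
the 0.1 learning rate is unstable for deep/wide stacks in our
implementation; with it, training is stable at the widths we use.

The forward and backward passes are implemented directly on numpy:
with 3 x 3 patches each convolution is a single dense matrix product
(im2col), so desk-scale training needs no deep-learning framework and
stays fast on one CPU core.  Arithmetic is float32; training is
deterministic for a fixed seed on a fixed BLAS.

### Transfer learning

`transfer_train` freezes every convolution except the last three and
refines those at initial learning rate 1e-4 (factor 0.1 unchanged).
Frozen weights are bit-identical before and after — this is a tested
contract, not an approximation.

### Whole-volume inference

`translate_volume` slides the k x k window at stride 1 across every
slice perpendicular to a chosen axis (volumes are edge-replicated at
borders so each voxel owns a centered patch).  Two aggregations:
`overlap-average` (default) sets each voxel to the mean of all patch
predictions covering it; `center-only` uses the center prediction of
the voxel's own patch.  Because the zero-padded convolutions make the
k x k positions inequivalent, the two aggregations agree only
approximately even on piecewise-constant inputs, and overlap-average
is constant on a constant volume only away from the one-voxel border.
The output is a single 3D volume; views along other axes are the same
data.

## Derived maps and baselines

* MTR = (M0 − Mt) / M0, with M0 ≤ eps voxels flagged invalid.
* Diffusion tensor: ordinary least squares of the log-signal on the six
  tensor elements plus log S0 (the log-linear method), eigenvalues by
  symmetric eigendecomposition, FA by the standard formula, radial
  diffusivity as the mean of the two minor eigenvalues, optional
  single-shell restriction.  No weighting or iteration by default.
* Kurtosis: with two shells sharing directions, the per-direction
  system `ln(S_b/S0) = −bD + b²D²K/6` is linear in `(D, D²K/6)` and
  solved exactly; MD and MK are direction means, K clamped to
  [−1, 10] with clamp counts reported.  The estimator choice
  (per-direction two-shell, then average) is a package decision.
* Polynomial baselines: OLS of the target on channel monomials of
  order 1 or 2 (order 2 adds squares and pairwise products).  Features
  are z-scored internally for conditioning; coefficients are reported
  in original units.  Rank-deficient designs raise an error naming the
  collinear features.

## The synthetic phantom

The phantom stands in for co-registered MRI + histology data with an
exact, known ground truth:

* **Geometry** — an ellipsoidal "brain" mask; tissue classes are
  equal-volume quantile bands of a Gaussian-smoothed random field
  (smoothness sets blob size).  A class with zero voxels warns rather
  than fails.
* **Signals** — per class and channel mean levels; across a designated
  "DWI-like" channel group a sinusoidal direction-to-direction
  oscillation with class-dependent amplitude and phase, emulating how
  diffusion signal varies across encoding directions differently in
  different tissue.  A smooth multiplicative per-channel modulation
  field (default relative amplitude 0.15) adds within-class signal
  variation; without it the per-voxel design would have only
  `n_classes` distinct rows and linear-mapping recovery from voxel
  data would be ill-posed.
* **Noise** — Rician: each voxel v becomes sqrt((v+n1)² + n2²) with
  n1, n2 ~ N(0, σ) and σ a stated fraction of the channel's
  within-mask mean absolute signal (the reference level is a package
  decision; it is recorded in every report).
* **Ground truth** — the target is the mapping (linear, quadratic,
  subset-dependent quadratic, or per-class lookup) applied to the
  *noise-free* signals, so recovery metrics are unambiguous.  Noise
  enters only the inputs.
* **Mismatch** — random in-plane displacement fields: independent
  Gaussian x/y components on a coarse control grid (default 1 mm) per
  slice, cubic-B-spline interpolated to all voxels; magnitudes at the
  control points are Chi-distributed with 2 degrees of freedom.
  Through-plane displacement is zero.  The default mean displacement
  is 1.5 voxels (scale = mean / sqrt(pi/2)), matching a "one to two
  voxel" residual registration error.

What the phantom does *not* emulate: MR physics (relaxation, real
sequences), anatomical geometry, spatially correlated noise, partial
volume at a real point-spread function.  Tests passing on phantoms
show that the algorithms are implemented correctly and that recovery
works under the stated noise/mismatch models — not that any
particular real acquisition carries enough information for a given
stain.

### Informative vs uninformative decoy channels

In a class-based phantom *every* channel whose class means differ
encodes the tissue class, so channels outside the mapping's active
set still carry information that is redundant with the active
channels.  A translation network may lean on them, and the
perturbation analysis then honestly reports shared contributions.
Exact recovery of the active set is therefore only well-posed when
decoy channels are uninformative; the phantom factory's
`uninformative_decoys` option gives decoys class-independent means
and no oscillation for precisely the channel-importance experiments.
This mirrors real multi-contrast data, where redundancy among the
diffusion-weighted images spreads contribution across many channels.

## Contribution analysis

For channel j: replace it by a Rician-noised copy (σ = 10% of the
channel's within-mask mean by default), re-translate the volume, and
record the within-mask RMSE against the unperturbed output; average
over `repeats` independent draws (deterministic per-(channel, repeat)
substreams) and normalize across channels to shares summing to 1.
Ranking is a stable descending sort (ties by channel index);
`select_subset` keeps the shortest ranking prefix reaching a coverage
target, and `acquisition_budget` prices it with per-channel
acquisition-time weights (uniform by default, since per-sequence
timings are protocol-specific).  Grouped summaries (e.g. T2W / MT /
low-b / high-b DWI) sum member contributions over a user manifest.

## Evaluation suite

RMSE and R² (squared Pearson correlation — sign-blind by definition,
so inspect the correlation sign separately) over within-mask voxels;
SSIM with a Gaussian window (sigma 1.5), dynamic range defaulting to
the within-mask reference range, averaged within the mask; ROC/AUC
against the reference binarized at its Otsu (between-class-variance
maximizing) threshold.  "Optimal thresholding" = Otsu is a package
decision; the threshold and method are recorded in every result.
Polarity is explicit: for AF-like stains the positive class is
hypo-intense.  The prediction's own polarity is a separate parameter
(defaulting to the reference's) so that a contrast-inverted
prediction can be scored after declaring its polarity; note that
flipping *both* label and score orientation leaves AUC unchanged, so
the two parameters are genuinely distinct.  t-SNE embeds flattened
per-patch predictions by default (intermediate-layer features are an
option) with deterministic subsampling and seeding.

## Problem sizes and numerical choices

Desk-scale experiments in the tests, examples and acceptance script
use 24³–48³ phantoms, 4–8 residual blocks and 16 channels per layer,
10–30 epochs, 6 000–20 000 patches.  At this scale the 0.1 learning
rate is bistable — depending on the data draw it either converges or
collapses to a constant predictor — so desk-scale runs use 0.05,
which was stable in every configuration scanned; the configuration
defaults (30 blocks, width 64, learning rate 0.1) remain unchanged.
Width 16 reaches held-out R² ≈ 0.99 on 48³ phantoms.  Other fixed
choices: learning-rate staircase boundaries at epochs 10, 20, …;
L1-loss gradient `sign(residual)/n`; ties in epoch selection resolved
to the earliest epoch; eligible patch centers sampled uniformly
without replacement; masks constrain only patch centers (surface
patches are kept — they form their own cluster in embeddings);
per-channel z-scoring fitted on training data only and stored with
the model; kurtosis clamp bounds [−1, 10].

## What the mismatch experiment does and does not show

Training against displacement-warped targets, the 3×3-patch network
fits the mismatched data with consistently lower held-out error than
single-voxel (k=1) training on identical patch centers: the patch
absorbs part of the registration error that a pointwise input–target
pairing cannot, which is the rationale for the small patch.

A stronger claim — that k=3 training also recovers the *true*
underlying mapping better than k=1 under mismatch — does **not** hold
in this phantom family, and we verified this across single- and
multi-volume training, modulation levels, noise fractions from 5% to
25%, and structure sizes.  The reason is structural: with an L1 loss,
k=1 training estimates the conditional median of the displaced target
given the center signals, and the median is robust to symmetric
displacement noise, so the k=1 model converges to the true mapping
almost unharmed.  The k=3 patch loss, by contrast, rewards predicting
displacement-blurred patches (and, when a single training volume is
used, lets the network memorize the one realized displacement field
through incidental positional cues such as smooth modulation
patterns).  On real data the balance may differ — stains are not
deterministic functions of the local signals, and mismatch is not the
only noise source — but phantom results on ground-truth recovery
under mismatch should be read with this in mind.

## The decoy-contribution floor

Perturbation contributions of channels the mapping does not use do
not reach zero in practice.  The perturbation sigma is 10% of a
channel's raw within-mask mean, while the network consumes z-scored
inputs; for a variance-poor decoy channel the same sigma is several
times larger in normalized units than for a high-contrast active
channel.  Combined with the residual sensitivity that finite training
leaves in place, decoys retain roughly 3–5% contribution each at
desk scale (insensitive to doubling the training length), so the
active channels' cumulative share saturates around 0.7 rather than
1.  Rankings are unaffected — active channels still come out on
top — but coverage-based subset selection over such a profile
necessarily includes several decoys before reaching high coverage
targets.

## Known limitations

* The numpy engine targets k ≈ 3 patches; it is not meant for large
  receptive fields or GPU-scale throughput.
* Stability of the 0.1 learning rate depends on network width; wide
  stacks may need a lower rate despite the scaled residual
  initialization (training aborts with guidance on non-finite loss).
* The displacement simulator is in-plane only, matching the
  coronal-plane registration-error model it reproduces.
* R² and SSIM are computed on within-mask voxels of a single volume;
  no across-subject statistics are provided.
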