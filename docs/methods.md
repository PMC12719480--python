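# Methods

`glioseg` implements a three-phase pipeline for binary tumor segmentation of
2-D brain-MRI-like slices, together with a synthetic phantom generator that
makes every stage testable without external data. This note records the model,
its assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Pipeline

**Phase 1 — generative autoencoder (GAE).** An encoder of stride-2
conv/batch-norm/ReLU stages compresses a slice by a factor of
`2^encoder_depth` per axis into a spatial latent map `Z = E(X)`; a mirrored
decoder (nearest-neighbour upsampling + convolution) reconstructs
`X' = D(Z)`. At the bottleneck the `h'·w'` positions are treated as tokens
and refined by single-head scaled dot-product self-attention,

    Attention(Q, K, V) = softmax(Q Kᵀ / √d_k) V,

with learned position-wise (1×1) projections for Q, K, V and a residual
connection. Training is unsupervised mean-squared-error reconstruction. MSE
is used because the target is a real-valued (z-scored) image; the latents are
plain (no KL regularization, no adversarial term) — the autoencoder is
reconstruction-only. Self-attention is applied at the bottleneck only; gates
in the decoder of the segmentation network (below) are a separate, additive
mechanism and the two are deliberately not conflated.

**Phase 2 — detection and coarse ROI.** A small residual CNN (stem conv +
residual blocks + global average pooling + linear head) produces two-class
logits; softmax gives `P(tumor)`, and a gate runs segmentation only when
`P(tumor) ≥ τ` (default τ = 0.5, the argmax rule). For positive cases,
k-means (Lloyd's algorithm with k-means++ seeding, `n_init = 10` deterministic
restarts, ties to the lowest cluster index, empty clusters re-seeded from the
farthest point) clusters the latent positions; the tumor-like cluster — the
minority cluster with the highest mean feature norm, on the reasoning that
lesions are small and high-salience — is upsampled nearest-neighbour to image
resolution as a coarse ROI. `k = 2` by default (lesion vs background); both
the rule and `k` are configurable. The classifier sees the image by default;
`input_kind="latent"` feeds it the GAE latent map instead (both paths are
wired and tested).

**Phase 3 — segmentation ensemble.** Two U-Net variants: (a) an
attention-gated U-Net whose skip connections are scaled per position by
`w = σ(ψ(ReLU(Wₓx + W_g g + b)))` with the upsampled deeper feature as gating
signal `g`; (b) a residual-encoder U-Net without gates. Member (a)'s encoder
convolutions are initialized from the pretrained GAE encoder where shapes
match; member (b) trains from scratch. Outputs are per-pixel sigmoid
probabilities fused by soft voting (weighted mean, equal weights by default)
and thresholded at 0.5. Training minimizes the hybrid loss

    L = α·L_BCE + (1−α)·L_Dice,
    L_BCE  = −mean[y·log ŷ + (1−y)·log(1−ŷ)],      ŷ clipped to [1e−7, 1−1e−7]
    L_Dice = 1 − (2·Σ y·ŷ + ε) / (Σ y + Σ ŷ + ε),   pooled over the batch

with Adam. α defaults to 0.5; it changes the balance between pixel-wise
accuracy (BCE) and region overlap (Dice), and `scripts/sweep_alpha.py` sweeps
{0.3, 0.5, 0.7} on identical data for inspection. ε = 1e−6 — small relative
to any realistic mask sum, and the ε/ε convention makes the empty-vs-empty
Dice loss exactly 0. The coarse ROI enters segmentation as an extra input
channel by default (`mask_input_channel`); `restrict_loss` instead evaluates
the loss only on ROI-or-truth pixels, and `off` disables it.

## Preprocessing and data discipline

Images are z-scored per image, `(X − μ)/σ`, with the population σ (no Bessel
correction) — per-dataset normalization is available by applying the returned
parameters externally. Resizing is bilinear for images and nearest-neighbour
for masks (preserves binarity). Augmentation draws rotation in ±10°,
translation in ±5 px per axis, and horizontal/vertical flips, applies the
identical geometric transform to image (bilinear) and mask (nearest), and is
a pure function of `(seed, draw_index)`. Rotation is about the image center
with constant-zero padding (zero padding avoids inventing tissue). Coordinate
conventions are fixed: row-major arrays, pixel centers at integer
coordinates, translations given as `(dx, dy)` = (columns, rows).

Splitting is stratified **and** subject-wise simultaneously: subjects (never
slices) are allocated to train/val/test per class by largest-remainder
rounding after a seeded shuffle, so subject sets are disjoint and each split
contains every class. Default fractions are 3655/5880, 914/5880, 1311/5880.
Augmentation happens after splitting, on the training split only; an
`augment_before_split` flag reproduces the alternative ordering in which
augmented copies are created before partitioning, which is kept only as an
explicit opt-in because it can leak near-duplicates across splits.

All stochastic components — phantom generation, splitting, initialization,
shuffling, augmentation, k-means seeding — derive independent streams from
one global seed (default 42) via `SeedSequence` spawning, so two runs of the
same configuration are bit-identical.

## Synthetic phantoms

The generator emulates what the pipeline consumes from a curated MRI slice
archive: subjects carrying several slices, a per-subject binary label, a
roughly elliptical bright lesion over smooth soft-tissue-like texture,
additive Gaussian noise, and controllable class imbalance. The lesion is an
axis-rotated ellipse with per-slice jitter of center and orientation; the
semi-axes are an **area-preserving** perturbation (`r·s`, `r/s`) of a
per-subject base radius, so the expected positive-pixel count is `π r²` and
analytically checkable. The background is a smoothed Gaussian random field
(correlation length `background_texture_scale`, amplitude
`background_texture_amp`) plus white noise of σ = `noise_sigma`.

Defaults (desk scale): 64×64 px, 50 subjects × 6 slices, prevalence 0.5,
radius 6–14 px, lesion contrast 0.5 over a 0.4-mean background, texture
amplitude 0.08, noise σ 0.05. Contrast ten times the noise makes the task
deliberately easy: the tests establish that the *pipeline machinery* learns,
gates, clusters and evaluates correctly, not that it would reach any
particular accuracy on clinical MRI. The phantoms omit MRI physics entirely —
no bias fields, no multi-sequence contrast, no skull or anatomy, no 3-D
structure, no annotation noise — so passing scores say nothing quantitative
about real-data performance.

## Training configuration

Reference recipe: Adam, learning rate 3e−4, batch size 8, up to 20 epochs,
early stopping on validation loss (patience in epochs, best weights
restored), He-normal initialization with deterministic seeding, global seed
42. The desk preset shrinks the problem to run on one CPU core in minutes:
64×64 inputs, GAE with 3 encoder stages (8→16→32 channels, attention dim 16),
U-Nets of depth 3 with 8 base channels, 6 epochs with patience 2 — and raises
the learning rate to 3e−3. The increase follows from the step budget: Adam's
per-parameter step is bounded by the learning rate, and a desk run makes only
a few hundred optimizer steps, an order of magnitude fewer than the reference
schedule assumes, so the step size must grow by roughly that factor for the
optimization to converge inside the budget. The reference values remain the
`TrainConfig` defaults.

## Evaluation

Dice `2|X∩Y|/(|X|+|Y|)`, Jaccard `|X∩Y|/|X∪Y|`, pixel-pooled sensitivity
`TP/(TP+FN)` and specificity `TN/(TN+FP)`, AUC-ROC of the tumor-presence
scores (Mann-Whitney form), and HD95 — the maximum of the two directed 95th
percentiles of boundary-to-boundary nearest-neighbour Euclidean distances,
optionally scaled by a pixel spacing. Pinned numerical conventions: the
percentile interpolates linearly between order statistics; a boundary pixel
is a positive pixel with ≥ 1 non-positive 4-neighbour, with off-image
neighbours counting as non-positive; two empty masks give Dice/Jaccard 1.0
with a warning; HD95 is undefined for an empty mask — per-sample it raises,
per-dataset the sample is skipped and counted in `hd95_undefined`. Empty
prediction against nonempty truth scores Dice 0. Segmentation metrics average
per sample (macro) by default; pooled (micro) is a flag. Classification
accuracy is the accuracy of the gate decisions against the slice labels.

## Ablation ladder

Five configurations run on identical data and seeds: plain U-Net; + GAE
pretraining; + attention gates; + latent k-means ROI; full ensemble with
classifier gating and soft voting. Disabled stages are pass-throughs (no gate
= always segment; no GAE = random-init encoders, no ROI). The ladder writes a
CSV with columns configuration, dice, jaccard, sensitivity, hd95.

## Problem sizes used by tests and the acceptance script

The test suite trains the full desk preset once (≈300 slices, ≈4–5 minutes on
one core) and shares it across tests; autoencoder-learning checks use 200
slices for 5 epochs; reproducibility re-runs use a 12-subject, 32×32
configuration; the acceptance script runs the desk preset end to end plus the
five-row ladder on a 24-subject reduction. These sizes are the package's own
desk-scale operating points.

## Implementation note

No deep-learning framework is used: the models run on a compact reverse-mode
automatic-differentiation core over numpy float64 arrays (`glioseg.nn`),
providing exactly the operations the architectures need (conv2d via im2col,
batch norm, nearest upsampling, concatenation, matmul, elementwise ops) plus
Adam. Its gradients are validated against central finite differences and its
convolution against `scipy.signal.correlate`. Everything around the models
uses the standard scientific stack: scikit-image/scipy for resampling and
geometry, scipy `cKDTree` for boundary distances, scikit-learn for AUC-ROC,
pandas for manifests, Pillow for PNG I/O.

## Known limitations

* The phantom model is a stand-in for curated MRI; nothing here claims the
  intensity statistics of real scans (see above).
* 2-D only; NIfTI volumes are not read (PNG/JPEG manifests are).
* The published operating point this design follows reports HD95 as both
  4.89 mm and 4.52 mm for apparently the same configuration; the discrepancy
  is noted, not resolved, and no HD95 target is asserted.
* Training-time "iterations" follow from epochs × data size; an independent
  iteration cap is not implemented.
* The alternative of clustering "a coarse segmentation output" instead of the
  latent map is undefined in the source description and is not implemented;
  only the latent variant exists.
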