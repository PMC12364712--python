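# Methods

## Translation model

The translator is a fully convolutional U-Net mapping an RGB H&E patch at
0.25 µm/px onto a C-channel marker image at 1 µm/px. The encoder has six
blocks (stride-2 convolution, kernel 3, batch norm, ReLU), reducing the
input 64×; the decoder has five blocks (nearest-neighbour 2× upsample +
stride-1 convolution, batch norm, ReLU), of which four upsample and one
preserves resolution. Stated this way the down/up counts are arithmetically
inconsistent with a 4× net reduction unless exactly one decoder block keeps
its resolution; that is the minimal reconciliation and the one implemented.
Skip connections concatenate encoder features at equal resolution into the
first four decoder stages. Output heads (3×3 convolution + sigmoid) sit at
the full, 1/2 and 1/4 marker-grid scales; the sigmoid matches targets that
are min–max normalized to [0, 1]. Weights use Xavier initialization.

The conditional discriminator concatenates the (real or generated) marker
stack with the H&E image average-pooled onto the marker grid, passes six
convolution blocks with spectral normalization and ReLU (strides 2,2,2,1,1,1
from the 32-px desk grid), and reduces a 1-channel score map to one scalar
per sample. Spectral normalization divides each weight by its largest
singular value, estimated by power iteration on the (F, C·k·k) unfolding;
the u/v estimates are buffers treated as constants by the graph, the
standard approximation.

## Objectives

* **Adversarial (least-squares, multiscale).** Labels are 1 = real,
  0 = generated. Lower-scale generator outputs are bilinearly upsampled to
  the full marker grid and scored by the single shared discriminator; the
  per-scale terms are averaged. The generator loss as printed in the
  source formulation omits the sum over scales while dividing by |S|; the
  evident intent (mean over scales) is implemented. The discriminator's
  real term enters once per scale, i.e. with total weight one after the
  1/|S| normalization. Generated inputs are detached inside the
  discriminator loss, so it never backpropagates into the translator.
* **Gaussian pyramid loss.** Each octave holds `n_gs` (default 3)
  progressively smoothed copies (separable Gaussian, σ = 1, radius ⌈3σ⌉,
  reflect boundaries); the next octave's primary is the 2× decimation of
  the most-smoothed copy. The loss is Σ_r w_r · mean|y₁ʳ − ŷ₁ʳ| over
  3 octaves with w_r = 1; the pyramid of the prediction is built only on
  the full output scale. Reflect padding keeps constants exactly constant,
  so constant-image identities hold to machine precision.
* **Patch-wise contrastive loss.** Each output channel is replicated to a
  pseudo-RGB image (the encoder interface is 3-channel) and encoded by a
  pluggable multi-layer feature encoder; the default is a small frozen
  randomly initialized conv net (3 layers, width 16) — random projections
  preserve enough geometry for patch discrimination while gradients flow to
  the generated image. Per layer, the same pixel locations are sampled for
  anchor (generated) and positive (real) features; negatives are the real
  features at the other sampled locations. Features pass a trainable linear
  projection head and are L2-normalized; InfoNCE uses τ = 0.07. The
  adaptive weight w_t = (1 − g(t/T)) + g(t/T)·h(sim(ẑ, z)) with g(u) = u,
  h(u) = clamp((u+1)/2, 0, 1), cosine similarity, is applied as a constant
  (detached) per-patch multiplier. Defaults: 3 layers, 64 patches
  (16 in the desk preset), negatives = the other patches of the same layer.
  The printed InfoNCE denominator misplaces the temperature on the negative
  term; the standard exp(z·z⁻/τ) is implemented.
* **R1 penalty.** E over the batch of ‖∇_y D(y|x)‖² at real samples. The
  inner gradient is built with graph-tracking enabled so the penalty's own
  gradient w.r.t. discriminator weights (double backprop) is exact; this is
  why the autodiff engine defines every backward pass in terms of
  differentiable primitives.
* **Totals.** L_G = L_G^adv + λ_gp L^gp + λ_contrast L^contrast with
  λ_gp = 5.0, λ_contrast = 1.0; L_D = L_D^adv + λ_R1 R1 with λ_R1 = 1.0.
  Any non-finite term aborts the step naming the term.

## Training

Adam (β₁ = 0.5, β₂ = 0.999), learning rates 0.004 (G) and 0.0008 (D),
alternating D/G updates, no learning-rate schedule, no gradient clipping.
The full-scale profile is 1024-px H&E / 256-px marker patches, batch 16,
100 epochs. The desk profile — the canonical test configuration — is
128→32 px patches, batch 4, 3 markers, base widths 10 (G) / 12 (D),
500 steps, 16 contrastive patches; it trains in roughly two minutes on one
CPU. Augmentation applies flips and right-angle rotations consistently to
both images (exactness-preserving on the grid), with color jitter
(per-channel scale and offset) on the H&E only; small translations arise
from the random crop sampling. Crops correspond under the 4× factor: the
marker origin is sampled and the H&E origin is 4× it. Training runs in
float32 (the default tensor dtype elsewhere is float64); checkpoints store
weights, optimizer state, RNG state and config, and resuming reproduces an
uninterrupted run's losses exactly because execution is pure numpy and
therefore deterministic given the seed.

## Preprocessing

Marker normalization (fit on the training split only, applied everywhere):
clip at the per-marker 99.9th percentile → arcsinh with cofactor 1 →
per-sample Otsu background threshold (computed after light Gaussian
smoothing, kernel 3 / σ 3, pooled over the sample's ROIs; values at or
below the threshold are zeroed) → centre/standardize → min–max to [0, 1].
Whether Otsu sees raw or arcsinh-transformed values is exposed as a flag
(default: arcsinh, following the pipeline order). A constant channel skips
standardization with a warning rather than producing NaN.

Rigid H&E↔marker registration maximizes mutual information (32×32 joint
histogram) over an exhaustive grid of integer translations (default ±25% of
the image side) and a configurable rotation set (right angles by default,
arbitrary angles supported); candidates with under 25% overlap are skipped.
Macenko stain normalization estimates the 2-vector stain basis from the
robust percentile angles in the top-2 OD eigenspace (OD = −log((I+1)/I₀)),
remaps concentrations so their 99th percentiles match the reference maxima,
and returns near-white tiles unchanged with a warning. Haematoxylin
extraction uses the standard H&E deconvolution matrix.

## Whole-slide inference

Tissue is segmented by Otsu thresholding of inverted luminance on a
thumbnail with morphological cleanup; polygons are exported in level-0
coordinates. Tiles (0-based, half-open, level-0 units) are kept when their
tissue fraction (computed exactly with a summed-area table) reaches the
threshold; coordinates are persisted as JSON for reproducibility. Tiles are
batched through the model and stitched onto the marker grid; with the
default overlap 0 stitching is byte-exact for local models, and an optional
overlap uses linear feather blending. Failing tiles are logged, skipped and
marked in the QC overlay. Output is a multi-channel pyramid (2×2 block
means per level) writable as a pyramidal TIFF.

## Evaluation metrics

PSNR = 10·log₁₀(L²/MSE), with +∞ as the documented sentinel for identical
images. SSIM uses population moments in a local uniform (default, window 7)
or Gaussian window, with C₁ = (0.01 L)², C₂ = (0.03 L)²; a single
full-image window mode gives the textbook one-window formula. MS-SSIM is
the weighted product of per-scale SSIM over dyadic scales (standard
5-scale weights, renormalized when fewer scales are used, 3 on the small
desk images); per-scale values are floored at 0 before exponentiation so
the score stays in [0, 1] — consequently the single-scale equivalence with
classic SSIM holds whenever SSIM ≥ 0. RMSE-SW is the root of the mean
per-window MSE over a sliding window (default 8×8, stride 8), which
degenerates to the global RMSE when the windows tile the image exactly.
Human-perception error rates are computed from recorded verdicts as the
overall, on-generated and on-real error percentages.

Spatial co-localization: per ROI, the Spearman correlation of every marker
pair on cell-level mean expressions (ties get average ranks; ROIs with a
constant marker are skipped for that pair), averaged across ROIs. Pairs are
retained when the |average ground-truth correlation| exceeds 0.15, and the
MSE between ground-truth and generated averages is reported over retained
pairs.

## Cell-level analyses

Pseudo-cells are disk means (default diameter 10 µm) around given nucleus
coordinates; disks are clipped at borders, out-of-bounds centers skipped.
Cell typing uses a random forest (100 trees, depth 30, OOB score exposed)
on the marker means. The joint t-SNE embeds up to 1000 subsampled cells per
ROI from both ground-truth and generated sources together (perplexity 50,
1000 iterations at full scale; smaller in tests), with display values
scaled and clipped at the 99th percentile. Immune phenotyping counts CD8⁺
T cells whose center pixel (half-open grid, rounded) falls in the
intratumoral or stromal compartment of the tumour centre, after removing
excluded regions, divided by the compartment area from the mask pixel
count (µm² at 1 µm/px). The hot/cold classifier is a random forest on
(iCD8, sCD8) under stratified 5-fold cross-validation reporting F1 and
macro AUROC mean ± sd.

## MIL survival models

Bags hold per-patch feature vectors (one matrix per modality). Gated
attention pooling computes aᵢ = softmax(wᵀ(tanh(V hᵢ) ⊙ σ(U hᵢ))) and
g = Σ aᵢhᵢ. Multimodal fusion first re-mixes each modality's instances by
co-attention (Ĥ = softmax(W_q P (W_k H)ᵀ/√d)·W_v H and mirrored), pools
each, concatenates the bag vectors and projects back to dimension d.
Survival uses J = 4 quartile time bins (cuts from the training split,
half-open intervals, censored patients binned by last follow-up, held-out
times clamped to the last bin), per-bin hazard h_j = σ(logit_j),
S(j) = Π_{k≤j}(1 − h_k), and the discrete-time NLL with censoring code
c = 0 for an observed death:
−c·log S(y) − (1−c)·log S(y−1) − (1−c)·log h(y), summed over the cohort.
As printed in the source formulation the two uncensored terms carry
positive signs; all three enter negatively here (the standard NLL of the
cited derivation — the closed-form toy value 0.693 confirms it).

The patient risk is the negative sum of the discrete survival
probabilities, −Σ_j S(j). The phrase "negative sum of all logits" taken
literally is anti-concordant with event times (high hazards → early death
→ *low* −Σ logits), which would invert every concordance statistic; the
cited implementation uses −Σ_j S(j), which has the concordant orientation
and is what this package implements.

Training: Adam, batch 1, early stopping on validation loss,
reduce-on-plateau; defaults lr 1e-4 (survival) / 5e-5 (subtype), scaled up
(2e-3) in the short desk-scale benchmarks. Evaluation: IPCW (Uno-type)
time-dependent concordance truncated at the 90th percentile of follow-up
(estimator choice exposed; Harrell's C is the documented fallback when the
IPCW weights are undefined), Kaplan–Meier curves for the median-risk split,
and the two-group log-rank test.

## Synthetic data generator

The simulator emulates the paired-serial-section regime: cells (default
140 on a 96-px canvas; mixture tumour 0.45, CD8 T 0.12, CD4 T 0.10, B 0.08,
endothelial 0.05, other 0.20, with tumour cells clustered in a blob) carry
per-type marker expression from a configurable matrix in [0, 1]. Marker
channels are sums of expression-weighted nucleus disks (radius 3 µm),
Gaussian-blurred (σ = 1 px), plus truncated Gaussian noise (sd 0.05)
clipped at 0 and min–max scaled to [0, 1]. The pseudo-H&E renders nuclei as
dark basophilic disks on an eosin-like background at 4× resolution — a
stylized two-color model, since only the morphology→marker correspondence
must be learnable — and receives a random affine jitter (default ±3 px,
±2°) standing in for slice-to-slice displacement; the exact inverse
transform is stored. Region masks derive from smoothed tumour-cell
density: support > 20% of peak, tumour centre = erosion of the support by a
margin (12 px default, a scaled-down analogue of a 500 µm exclusion),
intratumoral = centre ∧ density > 50% of peak, stromal = the remainder of
the centre; intratumoral and stromal are disjoint by construction.

The survival generator plants a latent score u ~ N(0,1) per patient,
risk = effect_size·u, event times exponential with rate exp(risk),
independent uniform censoring, quartile time bins, and embeds the risk
additively in the first 8 feature dimensions of every instance in both
modalities; effect size 0 therefore yields bags with no survival signal.

What the simulator does **not** emulate: real stain physics and scanner
variation, nucleus segmentation errors, spatial niches and cell–cell
interaction structure beyond one tumour blob, marker spillover/compensation
artifacts, and non-exponential hazards. Tests passing on it demonstrate
that the implementations are correct and that the pipelines recover planted
structure under the stated conditions — not clinical-grade performance on
real cohorts.

## Benchmark problem sizes and numerical choices

Desk-scale benchmark sizes, chosen once for single-CPU execution:
generative smoke = 3 training / 2 held-out ROIs (64-px marker canvas,
3 markers), 500 steps; co-localization = 20 ROIs × 2000 cells against
population Spearman values from a 200 000-draw simulation of the type
mixture; cell typing = 800 train / 800 test cells with disjoint-support
expression and measurement noise sd 0.1 (an image-derived variant at lower
density is reported alongside — overlapping pseudo-cell disks mix
neighbouring cells' signal, so it is informative rather than a separable
benchmark); survival = 200 patients (70/30 split), bag size 8, feature
dimension 16, censoring 0.2, effect sizes 0 and 4.

Numerical notes: tensors default to float64 (oracle-grade tests), training
uses float32; softmax subtracts a detached row max (shift-invariant, exact
gradient); log arguments in the survival NLL and cross-entropy are floored
at 1e-12; the spectral-norm divisor carries +1e-12 so an all-zero weight
stays zero; Spearman ties get average ranks; quartile cut points use linear
interpolation between order statistics; Otsu on a constant image raises.

## Known limitations

* Bitwise reproducibility holds for the pure-numpy execution here;
  heterogeneous BLAS builds may differ in the last bits across machines.
* The multiscale head placement and the 6-down/5-up reconciliation are one
  consistent reading of an underspecified architecture description.
* The contrastive default encoder is random and frozen; a pretrained
  encoder can be plugged in but none ships with the package.
* The HTA spatial-heterogeneity index is not implemented (its computation
  is defined externally and not specified by the source material).
* Deformable registration is out of scope; the MI matcher is rigid.
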