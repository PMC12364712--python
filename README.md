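# he2plex

Virtual multiplexed protein imaging from routine H&E histology.

Multiplexed protein imaging (for example imaging mass cytometry, IMC)
quantifies dozens of protein markers at ~1 µm resolution, but is slow,
expensive and restricted to small regions of interest. H&E staining is
cheap, fast and covers whole slides, but encodes protein expression only
implicitly through morphology. `he2plex` is a conditional-GAN framework that
translates H&E image patches into spatially resolved multi-channel
protein-marker images — an 11-marker melanoma panel by default (MelanA,
S100, gp100, SOX10, CD3, CD8a, CD20, CD16, CD31, HLA-ABC, HLA-DR) — plus the
full machinery around the model: marker normalization, mutual-information
ROI registration, tile-based whole-slide inference, full-reference image
metrics, pseudo-cell spatial analyses, immune phenotyping, and
attention-based multiple-instance survival models.

It is aimed at computational-pathology researchers who want a CPU-runnable,
fully testable reference implementation: a built-in tissue simulator
generates paired pseudo-H&E/marker images with known ground truth (planted
marker co-expression, cell types, region masks, affine slice-to-slice
misalignment, survival effect sizes), so every stage of the pipeline can be
validated without access to restricted clinical cohorts.

## The model

A translator G (fully convolutional U-Net: six stride-2 encoder blocks,
five decoder blocks of which four upsample 2×, sigmoid output heads at the
full, 1/2 and 1/4 marker-grid scales) maps an H&E patch x (0.25 µm/px) to a
C-channel marker stack on a 4× coarser grid (1 µm/px). A conditional
discriminator D (six spectral-normalized conv blocks, conditioned by
channel-concatenating the H&E average-pooled to the marker grid) is trained
against it with least-squares GAN objectives over the scale set S:

    L_G^adv = (1/|S|) Σ_s E[(D(G⁽ˢ⁾(x)|x) − 1)²]
    L_D^adv = (1/|S|) Σ_s E[(D(y|x) − 1)²] + E[D(G⁽ˢ⁾(x)|x)²]

Because consecutive tissue sections are never pixel-aligned, pixel-level
supervision uses a **Gaussian pyramid loss**: L1 distances between the
primary layers of Gaussian pyramids of y and ŷ, Σ_r w_r·E‖y₁ʳ − ŷ₁ʳ‖₁.
Patch-level supervision uses an **adaptive patch-wise InfoNCE loss**:
features of the generated image at sampled locations must match the real
image's features at the same locations against negatives from other
locations, weighted by w_t = (1 − g(t/T)) + g(t/T)·h(sim(ẑ, z)). The
discriminator additionally carries an R1 gradient penalty E‖∇_y D(y|x)‖².
Totals: L_G = L_G^adv + λ_gp·L^gp + λ_contrast·L^contrast (λ_gp = 5,
λ_contrast = 1); L_D = L_D^adv + λ_R1·R1 (λ_R1 = 1).

Downstream, marker stacks are turned into **pseudo-cells** (10 µm disk
means around nucleus coordinates), typed with a random forest, summarized
as marker-pair Spearman co-localization profiles, and used for immune
phenotyping (intratumoral/stromal CD8⁺ T-cell densities, hot vs cold).
For outcome prediction, per-patch features form bags for gated-attention
MIL with an optional co-attention fusion of H&E and marker modalities and a
discrete-time survival head (per-quartile hazards, NLL loss, IPCW
time-dependent C-index, Kaplan–Meier / log-rank evaluation).

All neural components run on a compact numpy autodiff engine
(`he2plex.nn`) with second-order gradient support (needed by R1), so the
package trains and evaluates on a single CPU with no deep-learning
framework dependency.

## Worked example

```python
import numpy as np
from he2plex.synthetic import TissueSimConfig, simulate_paired_roi, simulate_survival_cohort
from he2plex.evaluation import psnr, ms_ssim, rmse_sw
from he2plex.cells import extract_pseudo_cells
from he2plex import mil

roi, scene = simulate_paired_roi(TissueSimConfig(canvas_size=96, seed=7))
gt = scene.marker_stack.data
noisy = np.clip(gt + np.random.default_rng(0).normal(0, 0.05, gt.shape), 0, 1)
print(f"H&E image: {roi.he_image.shape}, marker stack: {gt.shape}")
print(f"PSNR    (MelanA): {psnr(gt[0], noisy[0]):.2f} dB")
print(f"MS-SSIM (MelanA): {ms_ssim(gt[0], noisy[0], n_scales=3):.4f}")
print(f"RMSE-SW (MelanA): {rmse_sw(gt[0], noisy[0]):.4f}")

cells = extract_pseudo_cells(scene.marker_stack, scene.centers, diameter_um=10)
print(f"pseudo-cells extracted: {len(cells)}")

bags = simulate_survival_cohort(200, bag_size=8, feature_dim=16,
                                effect_size=4.0, censor_rate=0.2, seed=0)
model, _ = mil.train_mil(bags[:140], mil.MilConfig(feature_dim=16, hidden=8,
                                                   n_out=4, seed=0),
                         epochs=15, lr=2e-3, seed=0)
risks = mil.predict_risks(model, bags[140:])
res = mil.evaluate_survival(risks,
                            np.array([b.time for b in bags[140:]]),
                            np.array([b.censor for b in bags[140:]]),
                            train_times=np.array([b.time for b in bags[:140]]),
                            train_censors=np.array([b.censor for b in bags[:140]]))
print(f"time-dependent C-index: {res['cindex']:.3f}   log-rank p: {res['logrank_p']:.2e}")
```

prints

```
H&E image: (384, 384, 3), marker stack: (11, 96, 96)
PSNR    (MelanA): 27.87 dB
MS-SSIM (MelanA): 0.8806
RMSE-SW (MelanA): 0.0404
pseudo-cells extracted: 140
time-dependent C-index: 0.888   log-rank p: 5.03e-09
```

The simulated ROI pairs a 384×384 pseudo-H&E image with an 11-channel
96×96 marker stack (the 4× resolution gap of the real modalities). The
three full-reference metrics quantify how close a (here: noise-corrupted)
marker stack is to the ground truth — higher PSNR/MS-SSIM and lower
RMSE-SW are better. The survival example plants a strong risk signal
(effect size 4) in the bag features; the gated-attention MIL model recovers
it with a held-out time-dependent C-index of 0.888, and the median-risk
split separates the Kaplan–Meier curves decisively (log-rank p ≈ 5×10⁻⁹).
With effect size 0 the same pipeline stays at chance level (C ≈ 0.5).

A thin CLI covers the common shell workflows:

```bash
he2plex simulate --out data/rois --n-rois 4 --seed 0
he2plex train    --data data/rois --seed 0 --out runs/desk --desk
he2plex evaluate --gt data/rois --pred data/rois --out report.csv
he2plex phenotype --cells data/rois/roi_000/cells.csv --masks data/rois/roi_000
```

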