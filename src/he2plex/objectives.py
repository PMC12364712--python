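"""Training objectives: multiscale least-squares adversarial losses, the
Gaussian pyramid reconstruction loss, the adaptive patch-wise contrastive
loss, and the R1 gradient penalty.

Conventions: labels are 1 for real and 0 for generated marker stacks; the
pyramid of a generated image is built only on the translator's full output
scale; lower-scale generator outputs are bilinearly upsampled to the full
marker grid before the shared discriminator scores them.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

BILINEAR_KERNEL = np.array([0.25, 0.5, 0.25])


@dataclasses.dataclass
class LossWeights:
    lambda_gp: float = 5.0
    lambda_contrast: float = 1.0
    lambda_r1: float = 1.0
    pyramid_weights: tuple = (1.0, 1.0, 1.0)   # w_r per octave
    n_gs: int = 3                               # smoothings per octave
    sigma: float = 1.0
    tau: float = 0.07
    n_patches: int = 64
    n_layers: int = 3


def upsample_bilinear2(x) -> Tensor:
    """Exact 2x bilinear upsampling (nearest + [1/4,1/2,1/4] smoothing)."""
    return ag.depthwise_blur(ag.upsample_nearest2(x), BILINEAR_KERNEL, "reflect")


def upsample_to(x, target_hw: tuple[int, int]) -> Tensor:
    x = ag.astensor(x)
    while x.shape[-1] < target_hw[1]:
        x = upsample_bilinear2(x)
    if x.shape[-2:] != tuple(target_hw):
        raise ValueError("upsample_to: incompatible sizes")
    return x


# ---------------------------------------------------------------------------
# adversarial losses (least-squares GAN over scales)
# ---------------------------------------------------------------------------

def _stack_scales(fakes: dict, x, detach: bool) -> tuple[Tensor, Tensor]:
    """Upsample every scale to the full marker grid and stack along batch."""
    full_hw = tuple(fakes[max(fakes)].shape[-2:])
    ups, xs = [], []
    for s in sorted(fakes, reverse=True):
        f = ag.astensor(fakes[s])
        if detach:
            f = f.detach()
        ups.append(upsample_to(f, full_hw))
        xs.append(ag.astensor(x))
    return ag.concat(ups, axis=0), ag.concat(xs, axis=0)


def adv_loss_G(disc: Callable, fakes: dict, x) -> Tensor:
    """L_G = mean over scales of E[(D(G^(s)(x)|x) − 1)^2].

    Lower-scale outputs are bilinearly upsampled to the full marker grid and
    scored by the single shared discriminator (batched across scales; the
    per-scale means coincide with the batched mean because all scales share
    the batch size).
    """
    if not fakes:
        raise ValueError("empty scale set")
    up_all, x_all = _stack_scales(fakes, x, detach=False)
    score = disc(up_all, x_all)
    return ag.tmean(ag.pow_const(score - 1.0, 2.0))


def adv_loss_D(disc: Callable, y, fakes: dict, x) -> Tensor:
    """L_D = mean over scales of E[(D(y|x) − 1)^2] + E[D(G^(s)(x)|x)^2].

    Generated inputs are detached: the discriminator loss never propagates
    into the translator.  The real term enters once per scale, i.e. with
    total weight one after the 1/|S| normalization.
    """
    if not fakes:
        raise ValueError("empty scale set")
    real_term = ag.tmean(ag.pow_const(disc(y, x) - 1.0, 2.0))
    up_all, x_all = _stack_scales(fakes, x, detach=True)
    fake_term = ag.tmean(ag.pow_const(disc(up_all, x_all), 2.0))
    return real_term + fake_term


# ---------------------------------------------------------------------------
# Gaussian pyramid loss
# ---------------------------------------------------------------------------

def gaussian_kernel1d(sigma: float) -> np.ndarray:
    radius = max(1, int(np.ceil(3.0 * sigma)))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_pyramid(image, n_octaves: int = 3, n_gs: int = 3,
                     sigma: float = 1.0, strict: bool = True) -> list:
    """Primary layer of each octave.

    Octave r holds `n_gs` progressively smoothed copies of its primary; the
    next octave's primary is the 2x decimation of the most-smoothed copy.
    Accepts numpy arrays or autograd tensors, 2-D or (N, C, H, W).
    """
    x = ag.astensor(image)
    squeeze = False
    if x.ndim == 2:
        x = ag.reshape(x, (1, 1) + x.shape)
        squeeze = True
    if min(x.shape[-2:]) < 2 ** (n_octaves - 1):
        if strict:
            raise ValueError("image too small for requested octaves")
        n_octaves = int(np.log2(min(x.shape[-2:]))) + 1
    k = gaussian_kernel1d(sigma)
    primaries = [x]
    cur = x
    for _ in range(n_octaves - 1):
        sm = cur
        for _ in range(n_gs):
            sm = ag.depthwise_blur(sm, k, "reflect")
        cur = ag.decimate2(sm)
        primaries.append(cur)
    if squeeze:
        primaries = [ag.reshape(p, p.shape[-2:]) for p in primaries]
    return primaries


def pyramid_loss(y, y_hat, weights: Sequence[float] = (1.0, 1.0, 1.0),
                 n_gs: int = 3, sigma: float = 1.0) -> Tensor:
    """Weighted sum over octaves of the mean absolute error of the primaries."""
    y = ag.astensor(y)
    y_hat = ag.astensor(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("pyramid_loss: shape mismatch")
    n_oct = len(weights)
    py = gaussian_pyramid(y, n_oct, n_gs, sigma)
    ph = gaussian_pyramid(y_hat, n_oct, n_gs, sigma)
    total = None
    for w_r, a, b in zip(weights, py, ph):
        term = ag.tmean(ag.tabs(a - b)) * float(w_r)
        total = term if total is None else total + term
    return total


# ---------------------------------------------------------------------------
# patch-wise contrastive loss
# ---------------------------------------------------------------------------

class RandomConvEncoder(nn.Module):
    """Small fixed random conv net exposing multi-layer features.

    Stands as the default pluggable feature encoder for the contrastive
    objective; weights are frozen (random projections preserve enough
    geometry for patch discrimination) while gradients still flow to the
    input image.
    """

    def __init__(self, in_channels: int = 3, width: int = 16,
                 n_layers: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.convs = []
        ch = in_channels
        for i in range(n_layers):
            conv = nn.Conv2d(ch, width, k=3, stride=(2 if i else 1), padding=1,
                             rng=rng)
            conv.weight.requires_grad = False
            conv.bias.requires_grad = False
            self.convs.append(conv)
            ch = width
        self.n_layers = n_layers
        self.width = width

    def forward(self, x) -> list:
        feats = []
        cur = x
        for conv in self.convs:
            cur = ag.relu(conv(cur))
            feats.append(cur)
        return feats


def info_nce(anchor: Tensor, positive: Tensor, tau: float = 0.07,
             weights: np.ndarray | None = None) -> Tensor:
    """Mean (optionally weighted) InfoNCE over P patches.

    anchor/positive: (P, d) L2-normalized rows; the negatives of anchor i
    are the positives at the other P−1 locations.
    """
    p = anchor.shape[0]
    if p < 2:
        raise ValueError("need >= 2 patches for negatives")
    logits = ag.matmul(anchor, ag.transpose(positive, None)) * (1.0 / tau)
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    lse = ag.tlog(ag.tsum(ag.texp(logits - shift), axis=1)) + ag.reshape(shift, (p,))
    eye = Tensor(np.eye(p))
    diag = ag.tsum(ag.mul(logits, eye), axis=1)
    per_anchor = lse - diag
    if weights is not None:
        per_anchor = ag.mul(per_anchor, Tensor(weights))
    return ag.tmean(per_anchor)


def _l2_normalize(z: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ag.pow_const(ag.tsum(ag.mul(z, z), axis=1, keepdims=True) + eps, 0.5)
    return ag.mul(z, ag.pow_const(norm, -1.0))


def linear_ramp(u: float) -> float:
    return float(u)


def similarity_weight(u: np.ndarray) -> np.ndarray:
    """h(u) = clamp((u+1)/2, 0, 1) applied to cosine similarities."""
    return np.clip((u + 1.0) / 2.0, 0.0, 1.0)


def patch_contrastive_loss(y_hat, y, encoder: RandomConvEncoder,
                           heads: list | None, *, tau: float = 0.07,
                           n_patches: int = 64, step: int = 0,
                           total_steps: int = 1,
                           rng: np.random.Generator | None = None,
                           schedule: Callable = linear_ramp,
                           weight_fn: Callable = similarity_weight) -> Tensor:
    """Adaptive patch-wise contrastive loss, summed over output channels.

    Each marker channel is replicated to a pseudo-RGB image before encoding
    (the encoder interface is 3-channel).  The same pixel locations are used
    for the anchor (generated) and positive (real) features; negatives are
    the real features at the other sampled locations of the same layer.
    The adaptive weight w_t = (1 − g(t/T)) + g(t/T)·h(sim(ẑ, z)) ramps from
    uniform to similarity-driven and is treated as a constant multiplier.
    """
    rng = rng or np.random.default_rng(0)
    y_hat = ag.astensor(y_hat)
    y = ag.astensor(y).detach()
    n, c, h, w = y_hat.shape
    g_t = schedule(step / max(total_steps, 1))

    # replicate each marker channel to pseudo-RGB and batch everything into a
    # single encoder call: rows 0..c*n-1 are generated, the rest are real
    def to_rgb_stack(img):
        mono = ag.reshape(ag.transpose(img, (1, 0, 2, 3)), (c * n, 1, h, w))
        return ag.concat([mono] * 3, axis=1)

    feats = encoder(ag.concat([to_rgb_stack(y_hat), to_rgb_stack(y)], axis=0))
    total = None
    n_terms = 0
    for li, f in enumerate(feats):
        hgrid = f.shape[-2] * f.shape[-1]
        k = min(n_patches, hgrid)
        if k < 2:
            raise ValueError("need at least 2 patch locations per layer")
        flat = ag.reshape(f, f.shape[:2] + (hgrid,))
        for ch in range(c):
            locs = rng.choice(hgrid, size=k, replace=False)
            for b in range(n):
                row = ch * n + b
                a2 = ag.transpose(ag.gather_last(flat[row], locs), (1, 0))
                p2 = ag.transpose(ag.gather_last(flat[c * n + row], locs), (1, 0))
                if heads is not None:
                    a2 = heads[li](a2)
                    p2 = heads[li](p2)
                a2 = _l2_normalize(a2)
                p2 = _l2_normalize(p2)
                sim = np.sum(a2.data * p2.data, axis=1)
                wt = (1.0 - g_t) + g_t * weight_fn(sim)
                term = info_nce(a2, p2, tau=tau, weights=wt)
                total = term if total is None else total + term
                n_terms += 1
    # mean over layers/patches/batch is inside info_nce + this normalization;
    # channels are summed per the objective definition
    return total * (float(c) / n_terms)


# ---------------------------------------------------------------------------
# R1 gradient penalty and total losses
# ---------------------------------------------------------------------------

def r1_penalty(disc: Callable, y, x) -> Tensor:
    """E over the batch of ||∇_y D(y|x)||²  (penalty at real samples)."""
    y_in = Tensor(np.asarray(ag.astensor(y).data), requires_grad=True)
    scores = disc(y_in, x)
    (gy,) = ag.grad(ag.tsum(scores), [y_in], create_graph=True)
    n = y_in.shape[0] if y_in.ndim == 4 else 1
    return ag.tsum(ag.mul(gy, gy)) * (1.0 / n)


def total_losses(adv_g, adv_d, gp, contrast, r1, weights: LossWeights
                 ) -> tuple[Tensor, Tensor, dict]:
    """L_G = L_G^adv + λ_gp L^gp + λ_contrast L^contrast;
    L_D = L_D^adv + λ_R1 R1.  Returns both plus a per-term breakdown."""
    terms = {"adv_G": adv_g, "adv_D": adv_d, "pyramid": gp,
             "contrast": contrast, "r1": r1}
    for name, t in terms.items():
        if t is not None and not np.isfinite(np.asarray(ag.astensor(t).data)).all():
            raise FloatingPointError(f"non-finite loss term: {name}")
    loss_g = ag.astensor(adv_g)
    if gp is not None and weights.lambda_gp:
        loss_g = loss_g + ag.astensor(gp) * weights.lambda_gp
    if contrast is not None and weights.lambda_contrast:
        loss_g = loss_g + ag.astensor(contrast) * weights.lambda_contrast
    loss_d = ag.astensor(adv_d)
    if r1 is not None and weights.lambda_r1:
        loss_d = loss_d + ag.astensor(r1) * weights.lambda_r1
    breakdown = {k: (float(ag.astensor(v).data) if v is not None else None)
                 for k, v in terms.items()}
    breakdown["L_G"] = float(loss_g.data)
    breakdown["L_D"] = float(loss_d.data)
    return loss_g, loss_d, breakdown
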