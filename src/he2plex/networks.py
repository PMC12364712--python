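"""Translator (multiscale U-Net) and conditional spectral-norm discriminator.

The translator maps an RGB H&E patch onto a C-channel marker stack whose
grid is ``he_scale_factor`` (default 4) times coarser, mirroring the
0.25 µm/px → 1 µm/px resolution gap.  Six stride-2 encoder blocks reduce by
64×; of the five decoder blocks four upsample 2× and one preserves
resolution, for a net 16× recovery — the minimal arithmetic that yields the
required 4× reduction.  Output heads (sigmoid, so predictions live in
[0, 1] like the min–max-normalized targets) are attached at the full, 1/2
and 1/4 marker-grid scales for multiscale adversarial supervision.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .nn import autograd as ag


@dataclasses.dataclass
class TranslatorConfig:
    in_channels: int = 3
    out_channels: int = 11
    base_width: int = 32
    max_width_mult: int = 4
    n_encoder: int = 6
    n_decoder: int = 5
    he_scale_factor: int = 4
    n_scales: int = 3
    seed: int = 0


@dataclasses.dataclass
class DiscriminatorConfig:
    marker_channels: int = 11
    cond_channels: int = 3
    base_width: int = 32
    max_width_mult: int = 4
    n_blocks: int = 6
    he_scale_factor: int = 4
    n_power_iterations: int = 1
    seed: int = 0


class Translator(nn.Module):
    def __init__(self, config: TranslatorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cap = config.base_width * config.max_width_mult
        widths = [min(config.base_width * 2 ** i, cap)
                  for i in range(config.n_encoder)]
        self.enc_convs, self.enc_bns = [], []
        in_ch = config.in_channels
        for w_ in widths:
            self.enc_convs.append(nn.Conv2d(in_ch, w_, k=3, stride=2, padding=1,
                                            rng=rng))
            self.enc_bns.append(nn.BatchNorm2d(w_))
            in_ch = w_
        # decoder: 4 upsampling blocks (with encoder skips) + 1 resolution-preserving
        self.dec_convs, self.dec_bns = [], []
        dec_widths = widths[-2::-1][:config.n_decoder - 1] + [widths[0]]
        ch = widths[-1]
        self.skip_src = []  # encoder stage index concatenated at each decoder stage
        for i in range(config.n_decoder - 1):
            skip_idx = config.n_encoder - 2 - i
            skip_ch = widths[skip_idx] if skip_idx >= 0 else 0
            self.skip_src.append(skip_idx)
            out_ch = dec_widths[i]
            self.dec_convs.append(nn.Conv2d(ch + skip_ch, out_ch, k=3, stride=1,
                                            padding=1, rng=rng))
            self.dec_bns.append(nn.BatchNorm2d(out_ch))
            ch = out_ch
        self.skip_src.append(-1)  # final block: no skip
        self.dec_convs.append(nn.Conv2d(ch, dec_widths[-1], k=3, stride=1,
                                        padding=1, rng=rng))
        self.dec_bns.append(nn.BatchNorm2d(dec_widths[-1]))
        # output heads at full, 1/2, 1/4, ... of the marker grid
        n_dec = config.n_decoder
        self.head_stage = {}  # scale -> decoder stage index
        for s in range(config.n_scales):
            # stage resolutions: H/32, H/16, H/8, H/4, H/4 (for 6 enc / 5 dec)
            stage = n_dec - 1 if s == 0 else n_dec - 1 - 1 - s
            self.head_stage[0.5 ** s] = stage
        self.heads = [nn.Conv2d(dec_widths[min(st, len(dec_widths) - 1)],
                                config.out_channels, k=3, stride=1, padding=1,
                                rng=rng)
                      for st in [self.head_stage[0.5 ** s]
                                 for s in range(config.n_scales)]]
        self.scales = [0.5 ** s for s in range(config.n_scales)]

    def forward(self, x) -> dict:
        """Returns {scale: output tensor in [0,1]} for scale in {1, 1/2, 1/4}."""
        x = ag.astensor(x)
        h = x.shape[-1]
        div = 2 ** self.config.n_encoder
        if x.shape[-1] % div or x.shape[-2] % div:
            raise ValueError(f"input spatial size must be divisible by {div}")
        feats = []
        cur = x
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            cur = ag.relu(bn(conv(cur)))
            feats.append(cur)
        outputs_by_stage = {}
        for i, (conv, bn) in enumerate(zip(self.dec_convs, self.dec_bns)):
            if i < self.config.n_decoder - 1:
                cur = ag.upsample_nearest2(cur)
                skip_idx = self.skip_src[i]
                if skip_idx >= 0:
                    cur = ag.concat([cur, feats[skip_idx]], axis=1)
            cur = ag.relu(bn(conv(cur)))
            outputs_by_stage[i] = cur
        out = {}
        for scale, head in zip(self.scales, self.heads):
            stage = self.head_stage[scale]
            out[scale] = ag.sigmoid(head(outputs_by_stage[stage]))
        return out


class Discriminator(nn.Module):
    """Conditional critic: scores a marker stack given the H&E it came from.

    The H&E conditioning image is average-pooled onto the marker grid and
    channel-concatenated with the (real or generated) marker stack.  Every
    convolution carries spectral normalization.
    """

    def __init__(self, config: DiscriminatorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cap = config.base_width * config.max_width_mult
        strides = [2, 2, 2] + [1] * (config.n_blocks - 3)
        in_ch = config.marker_channels + config.cond_channels
        self.convs = []
        for i in range(config.n_blocks):
            out_ch = min(config.base_width * 2 ** min(i, 3), cap)
            self.convs.append(nn.Conv2d(in_ch, out_ch, k=3,
                                        stride=strides[i], padding=1,
                                        spectral_norm=True,
                                        n_power_iterations=config.n_power_iterations,
                                        rng=rng))
            in_ch = out_ch
        self.final = nn.Conv2d(in_ch, 1, k=1, stride=1, padding=0,
                               spectral_norm=True,
                               n_power_iterations=config.n_power_iterations,
                               rng=rng)

    def forward(self, y, x_he):
        y = ag.astensor(y)
        x_he = ag.astensor(x_he)
        f = self.config.he_scale_factor
        cond = ag.avg_pool2d(x_he, f) if f > 1 else x_he
        if cond.shape[-2:] != y.shape[-2:]:
            raise ValueError("spatial mismatch between markers and resampled H&E")
        cur = ag.concat([y, cond], axis=1)
        for conv in self.convs:
            cur = ag.relu(conv(cur))
        score_map = self.final(cur)
        return ag.tmean(score_map, axis=(1, 2, 3))  # per-sample scalar


def build_translator(config: TranslatorConfig) -> Translator:
    return Translator(config)


def build_discriminator(config: DiscriminatorConfig) -> Discriminator:
    return Discriminator(config)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, translator: Translator,
                    discriminator: Discriminator | None = None,
                    extra: dict | None = None):
    path = Path(path)
    arrays = {f"G.{k}": v for k, v in translator.state_arrays().items()}
    if discriminator is not None:
        arrays.update({f"D.{k}": v for k, v in discriminator.state_arrays().items()})
    meta = {"translator_config": dataclasses.asdict(translator.config)}
    if discriminator is not None:
        meta["discriminator_config"] = dataclasses.asdict(discriminator.config)
    if extra:
        meta["extra"] = extra
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> tuple[Translator, Discriminator | None, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        g_cfg = TranslatorConfig(**meta["translator_config"])
        translator = Translator(g_cfg)
        translator.load_state_arrays(
            {k[2:]: data[k] for k in data.files if k.startswith("G.")})
        discriminator = None
        if "discriminator_config" in meta:
            discriminator = Discriminator(
                DiscriminatorConfig(**meta["discriminator_config"]))
            discriminator.load_state_arrays(
                {k[2:]: data[k] for k in data.files if k.startswith("D.")})
    return translator, discriminator, meta.get("extra", {})
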