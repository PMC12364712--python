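"""Adversarial training loop: paired patch sampling, augmentation,
alternating D/G updates with Adam, JSONL loss logging and checkpointing.

Two named profiles exist: the full-scale profile (1024 px H&E / 256 px
marker patches, batch 16, 100 epochs) and a desk profile (128/32, batch 4,
~500 steps, 3 markers, narrow widths) sized for a single CPU; the desk
profile is the canonical test configuration.
"""
from __future__ import annotations

import dataclasses
import json
import pickle
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.optim import Adam
from . import networks, objectives
from .networks import Translator, TranslatorConfig, Discriminator, DiscriminatorConfig
from .objectives import LossWeights, RandomConvEncoder
from .synthetic import PairedROI


@dataclasses.dataclass
class AugmentFlags:
    flip: bool = True
    rotate90: bool = True
    color: bool = True


@dataclasses.dataclass
class TrainConfig:
    he_patch: int = 1024
    marker_patch: int = 256
    batch_size: int = 16
    steps: int = 0                 # 0 -> use epochs * steps_per_epoch
    epochs: int = 100
    steps_per_epoch: int = 100
    lr_g: float = 0.004
    lr_d: float = 0.0008
    beta1: float = 0.5
    beta2: float = 0.999
    translator_base_width: int = 32
    disc_base_width: int = 32
    marker_channels: int = 11
    he_scale_factor: int = 4
    augment: AugmentFlags = dataclasses.field(default_factory=AugmentFlags)
    weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    checkpoint_every: int = 0      # 0 -> only final
    seed: int = 0
    dtype: str = "float32"         # training precision
    encoder_width: int = 16
    contrast_heads_dim: int = 16
    contrast_patches: int = 16

    def total_steps(self) -> int:
        return self.steps if self.steps else self.epochs * self.steps_per_epoch

    def validate(self):
        if self.he_patch != self.marker_patch * self.he_scale_factor:
            raise ValueError("patch-size ratio must equal he_scale_factor")
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be positive")


def desk_config(**overrides) -> TrainConfig:
    """CPU-scale preset: 128->32 px patches, 3 markers, narrow networks."""
    cfg = TrainConfig(he_patch=128, marker_patch=32, batch_size=4, steps=500,
                      translator_base_width=10, disc_base_width=12,
                      marker_channels=3, contrast_patches=16)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# sampling + augmentation
# ---------------------------------------------------------------------------

def sample_training_pair(roi_store: list[PairedROI], rng: np.random.Generator,
                         he_patch: int = 1024, marker_patch: int = 256
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Random spatially-corresponding crop pair (H&E origin = 4x marker origin)."""
    roi = roi_store[rng.integers(len(roi_store))]
    f = he_patch // marker_patch
    c, mh, mw = roi.marker_stack.data.shape
    if mh < marker_patch or mw < marker_patch:
        raise ValueError("ROI smaller than requested crop")
    oy = int(rng.integers(0, mh - marker_patch + 1))
    ox = int(rng.integers(0, mw - marker_patch + 1))
    marker = roi.marker_stack.data[:, oy:oy + marker_patch, ox:ox + marker_patch]
    he = roi.he_image[oy * f:oy * f + he_patch, ox * f:ox * f + he_patch]
    return he.copy(), marker.copy()


def augment_pair(he: np.ndarray, marker: np.ndarray, flags: AugmentFlags,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Geometric ops applied consistently to both images; color jitter H&E only."""
    if flags.flip and rng.random() < 0.5:
        he, marker = he[:, ::-1].copy(), marker[:, :, ::-1].copy()
    if flags.flip and rng.random() < 0.5:
        he, marker = he[::-1].copy(), marker[:, ::-1].copy()
    if flags.rotate90:
        k = int(rng.integers(4))
        he = np.rot90(he, k, axes=(0, 1)).copy()
        marker = np.rot90(marker, k, axes=(1, 2)).copy()
    if flags.color:
        scale = rng.uniform(0.92, 1.08, size=3)
        offset = rng.uniform(-0.03, 0.03, size=3)
        he = np.clip(he * scale + offset, 0.0, 1.0)
    return he, marker


def _make_batch(roi_store, rng, cfg: TrainConfig):
    xs, ys = [], []
    for _ in range(cfg.batch_size):
        he, marker = sample_training_pair(roi_store, rng, cfg.he_patch,
                                          cfg.marker_patch)
        he, marker = augment_pair(he, marker, cfg.augment, rng)
        xs.append(np.transpose(he, (2, 0, 1)))
        ys.append(marker)
    return np.stack(xs), np.stack(ys)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainResult:
    translator: Translator
    discriminator: Discriminator
    logs: list
    checkpoint: Path | None


def build_models(cfg: TrainConfig) -> tuple[Translator, Discriminator]:
    g_cfg = TranslatorConfig(out_channels=cfg.marker_channels,
                             base_width=cfg.translator_base_width,
                             he_scale_factor=cfg.he_scale_factor,
                             seed=cfg.seed)
    d_cfg = DiscriminatorConfig(marker_channels=cfg.marker_channels,
                                base_width=cfg.disc_base_width,
                                he_scale_factor=cfg.he_scale_factor,
                                seed=cfg.seed + 1)
    return Translator(g_cfg), Discriminator(d_cfg)


def train(cfg: TrainConfig, roi_store: list[PairedROI],
          out_dir: str | Path | None = None,
          resume_from: str | Path | None = None,
          max_steps: int | None = None) -> TrainResult:
    """Alternating least-squares GAN training.

    Deterministic given `cfg.seed` (pure-numpy execution).  On NaN in any
    loss term the run aborts with a diagnostic snapshot (when `out_dir` is
    set) identifying the offending term.
    """
    cfg.validate()
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    with ag.default_dtype(np.dtype(cfg.dtype)):
        return _train_impl(cfg, roi_store, out, resume_from, max_steps)


def _train_impl(cfg, roi_store, out, resume_from, max_steps):
    translator, disc = build_models(cfg)
    encoder = None
    heads = None
    use_contrast = cfg.weights.lambda_contrast > 0
    if use_contrast:
        encoder = RandomConvEncoder(3, cfg.encoder_width,
                                    cfg.weights.n_layers, seed=cfg.seed + 2)
        import he2plex.nn as nn_mod
        hrng = np.random.default_rng(cfg.seed + 3)
        heads = [nn_mod.Linear(cfg.encoder_width, cfg.contrast_heads_dim, rng=hrng)
                 for _ in range(cfg.weights.n_layers)]

    g_params = translator.parameters()
    if heads is not None:
        g_params = g_params + [p for h in heads for p in h.parameters()]
    d_params = disc.parameters()
    opt_g = Adam(g_params, lr=cfg.lr_g, betas=(cfg.beta1, cfg.beta2))
    opt_d = Adam(d_params, lr=cfg.lr_d, betas=(cfg.beta1, cfg.beta2))
    rng = np.random.default_rng(cfg.seed)
    start_step = 0
    logs: list[dict] = []

    if resume_from is not None:
        blob = pickle.loads(Path(resume_from).read_bytes())
        translator.load_state_arrays(blob["G"])
        disc.load_state_arrays(blob["D"])
        if heads is not None and "heads" in blob:
            for h, st in zip(heads, blob["heads"]):
                h.load_state_arrays(st)
        opt_g.load_state(blob["opt_g"])
        opt_d.load_state(blob["opt_d"])
        rng.bit_generator.state = blob["rng_state"]
        start_step = blob["step"]
        logs = list(blob.get("logs", []))

    total_steps = cfg.total_steps()
    end_step = min(total_steps, start_step + max_steps) if max_steps else total_steps

    def save_state(path: Path, step: int):
        blob = {"G": translator.state_arrays(), "D": disc.state_arrays(),
                "opt_g": opt_g.state(), "opt_d": opt_d.state(),
                "rng_state": rng.bit_generator.state, "step": step,
                "logs": logs, "config": dataclasses.asdict(cfg)}
        if heads is not None:
            blob["heads"] = [h.state_arrays() for h in heads]
        path.write_bytes(pickle.dumps(blob))

    translator.train()
    disc.train()
    log_fh = open(out / "losses.jsonl", "a") if out else None
    try:
        for step in range(start_step, end_step):
            x_np, y_np = _make_batch(roi_store, rng, cfg)
            x = Tensor(x_np)
            y = Tensor(y_np)

            fakes = translator(x)
            # --- D update ---------------------------------------------------
            adv_d = objectives.adv_loss_D(disc, y, fakes, x)
            r1 = objectives.r1_penalty(disc, y, x) if cfg.weights.lambda_r1 else None
            loss_d = adv_d if r1 is None else adv_d + r1 * cfg.weights.lambda_r1
            if not np.isfinite(loss_d.data):
                _abort_nan(out, translator, disc, step, "L_D",
                           {"adv_D": float(adv_d.data),
                            "r1": float(r1.data) if r1 is not None else None})
            gd = ag.grad(loss_d, d_params)
            opt_d.step(gd)

            # --- G update (discriminator frozen) ----------------------------
            adv_g = objectives.adv_loss_G(disc, fakes, x)
            gp = objectives.pyramid_loss(y, fakes[1.0],
                                         weights=cfg.weights.pyramid_weights,
                                         n_gs=cfg.weights.n_gs,
                                         sigma=cfg.weights.sigma) \
                if cfg.weights.lambda_gp else None
            contrast = None
            if use_contrast:
                contrast = objectives.patch_contrastive_loss(
                    fakes[1.0], y, encoder, heads, tau=cfg.weights.tau,
                    n_patches=cfg.contrast_patches, step=step,
                    total_steps=total_steps, rng=rng)
            loss_g, _, breakdown = objectives.total_losses(
                adv_g, adv_d.detach(), gp, contrast, r1, cfg.weights)
            gg = ag.grad(loss_g, g_params)
            opt_g.step(gg)

            breakdown["step"] = step
            logs.append(breakdown)
            if log_fh:
                log_fh.write(json.dumps(breakdown) + "\n")
            if out and cfg.checkpoint_every and (step + 1) % cfg.checkpoint_every == 0:
                save_state(out / f"ckpt_{step + 1:06d}.pkl", step + 1)
    finally:
        if log_fh:
            log_fh.close()

    ckpt = None
    if out:
        ckpt = out / "ckpt_latest.pkl"
        save_state(ckpt, end_step)
    return TrainResult(translator=translator, discriminator=disc, logs=logs,
                       checkpoint=ckpt)


def _abort_nan(out, translator, disc, step, term, breakdown):
    if out:
        networks.save_checkpoint(out / f"nan_snapshot_{step}.npz", translator,
                                 disc, extra={"step": step, "term": term,
                                              "breakdown": breakdown})
    raise FloatingPointError(f"NaN loss at step {step} in {term}: {breakdown}")


def translate(translator: Translator, he: np.ndarray) -> np.ndarray:
    """Inference: (H, W, 3) H&E in [0,1] -> (C, H/4, W/4) marker prediction."""
    translator.eval()
    x = Tensor(np.transpose(he, (2, 0, 1))[None])
    with ag.no_grad():
        out = translator(x)[1.0]
    translator.train()
    return out.data[0]
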