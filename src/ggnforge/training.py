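"""Adversarial training of the inpainting generator with two discriminators.

Each step draws a batch of training pairs and alternates: (1) both
discriminators update on (target = real, generated = fake), the ROI
discriminator seeing the fixed-size crops; (2) the generator updates on the
four-term objective (SSIM + adversarial, whole image and ROI).  Everything
is seeded, so a run is a pure function of (pairs, config, seed) and loss
histories replay bit-identically.
"""

from __future__ import annotations

import csv
import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .gan import (
    GANConfig,
    Discriminator,
    Generator,
    LossBreakdown,
    build_discriminator,
    build_generator,
    composite,
    crop_roi,
    ssim_loss_t,
)
from .types import Box, CTSlice, TrainingPair

__all__ = [
    "TrainState", "train_gan", "generate_synthetic",
    "save_checkpoint", "load_checkpoint", "TrainingDivergedError",
]

class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainState:
    step: int
    config: GANConfig
    generator: Generator
    d_whole: Discriminator
    d_roi: Discriminator
    history: list[dict] = field(default_factory=list)
    seed_chain: list[int] = field(default_factory=list)

    def history_csv(self) -> str:
        cols = ["step", "l_ssim_whole", "l_adv_whole", "l_ssim_roi", "l_adv_roi",
                "total", "d_whole", "d_roi"]
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=cols)
        writer.writeheader()
        for row in self.history:
            writer.writerow({k: row[k] for k in cols})
        return buf.getvalue()


def _batch_tensor(pairs: list[TrainingPair], idx: np.ndarray, attr: str) -> nn.Tensor:
    arr = np.stack([getattr(pairs[i], attr).pixels for i in idx])[:, None]
    return nn.Tensor(arr.astype(np.float32))


def _adv_t(scores: nn.Tensor, reduction: str) -> nn.Tensor:
    clipped = scores  # scores already strictly inside (0, 1)
    loss = -(clipped.log()).sum()
    if reduction == "mean":
        loss = loss * (1.0 / scores.data.size)
    return loss


def _bce_t(real: nn.Tensor, fake: nn.Tensor, smooth: bool) -> nn.Tensor:
    r_target, f_target = (0.9, 0.1) if smooth else (1.0, 0.0)
    l_real = -(r_target * real.log() + (1 - r_target) * (1.0 - real).log()).sum()
    l_fake = -((1 - f_target) * (1.0 - fake).log() + f_target * fake.log()).sum()
    return l_real + l_fake


def _crop_batch(images: nn.Tensor, boxes: list[Box]) -> nn.Tensor:
    crops = [crop_roi(images[i], boxes[i]) for i in range(images.shape[0])]
    size = crops[0].shape[-1]
    acc = [c.reshape(1, 1, size, size) for c in crops]
    out = acc[0]
    if len(acc) > 1:
        # stack via summed zero-padded embeddings is wasteful; concat by index
        n = len(acc)
        data = np.zeros((n, 1, size, size), dtype=np.float32)
        stacked = nn.Tensor(data, requires_grad=any(c.requires_grad for c in acc))
        # build graph manually: out[i] = acc[i]
        parents = tuple(c for c in acc if c.requires_grad)
        for i, c in enumerate(acc):
            data[i] = c.data[0]

        def backward(g, crops_=acc):
            for i, c in enumerate(crops_):
                if c.requires_grad:
                    c._acc(g[i][None])

        stacked._prev = parents
        stacked._backward = backward if parents else None
        return stacked
    return out


def train_gan(
    pairs: list[TrainingPair],
    config: GANConfig,
    out_dir: str | Path | None = None,
) -> TrainState:
    """Run the adversarial loop; returns the final state with full history."""
    if not pairs:
        raise ValueError("at least one training pair is required")
    size = pairs[0].target_image.shape
    if any(p.target_image.shape != size for p in pairs):
        raise ValueError("all pairs must share one image size")
    if size[0] != config.image_size:
        raise ValueError(
            f"pairs are {size[0]}x{size[1]} but config.image_size is {config.image_size}"
        )

    rng = np.random.default_rng(config.seed)
    gen = build_generator(config)
    d_whole = build_discriminator(config, "whole")
    d_roi = build_discriminator(config, "roi")
    opt_g = nn.Adam(gen.parameters(), lr=config.learning_rate, betas=config.adam_betas)
    opt_d = nn.Adam(d_whole.parameters() + d_roi.parameters(),
                    lr=config.learning_rate, betas=config.adam_betas)

    state = TrainState(step=0, config=config, generator=gen,
                       d_whole=d_whole, d_roi=d_roi)
    out_dir = Path(out_dir) if out_dir is not None else None

    n = len(pairs)
    for step in range(1, config.steps + 1):
        batch_seed = int(rng.integers(0, 2**31 - 1))
        state.seed_chain.append(batch_seed)
        idx = np.random.default_rng(batch_seed).choice(
            n, size=min(config.batch_size, n), replace=False
        )
        boxes = [pairs[i].roi_box for i in idx]
        x = _batch_tensor(pairs, idx, "input_image")
        target = _batch_tensor(pairs, idx, "target_image")

        # ---- discriminator update (generator frozen via detach) ----------
        fake = gen(x).detach()
        d_whole.zero_grad(); d_roi.zero_grad()
        dw_loss = _bce_t(d_whole(target), d_whole(fake), config.label_smoothing)
        dr_loss = _bce_t(
            d_roi(_crop_batch(target, boxes)),
            d_roi(_crop_batch(fake, boxes)),
            config.label_smoothing,
        )
        d_loss = dw_loss + dr_loss
        d_loss.backward()
        opt_d.step()
        opt_d.zero_grad()

        # ---- generator update --------------------------------------------
        gen.zero_grad(); d_whole.zero_grad(); d_roi.zero_grad()
        generated = gen(x)
        l_ssim_whole = ssim_loss_t(generated, target, mode=config.ssim_mode)
        gen_roi = _crop_batch(generated, boxes)
        tgt_roi = _crop_batch(target, boxes)
        l_ssim_roi = ssim_loss_t(gen_roi, tgt_roi, mode=config.ssim_mode)
        l_adv_whole = _adv_t(d_whole(generated), config.adv_reduction)
        l_adv_roi = _adv_t(d_roi(gen_roi), config.adv_reduction)
        g_loss = l_ssim_whole + l_adv_whole + l_ssim_roi + l_adv_roi
        g_loss.backward()
        opt_g.step()
        opt_g.zero_grad()
        d_whole.zero_grad(); d_roi.zero_grad()

        breakdown = LossBreakdown(
            l_ssim_whole=float(l_ssim_whole.data),
            l_adv_whole=float(l_adv_whole.data),
            l_ssim_roi=float(l_ssim_roi.data),
            l_adv_roi=float(l_adv_roi.data),
        )
        if not np.isfinite(breakdown.total) or not np.isfinite(float(d_loss.data)):
            raise TrainingDivergedError(f"non-finite loss at step {step}")
        state.history.append({
            "step": step,
            "l_ssim_whole": breakdown.l_ssim_whole,
            "l_adv_whole": breakdown.l_adv_whole,
            "l_ssim_roi": breakdown.l_ssim_roi,
            "l_adv_roi": breakdown.l_adv_roi,
            "total": breakdown.total,
            "d_whole": float(dw_loss.data),
            "d_roi": float(dr_loss.data),
        })
        state.step = step

        if (out_dir is not None and config.checkpoint_interval
                and step % config.checkpoint_interval == 0):
            save_checkpoint(state, out_dir / f"checkpoint-{step:06d}.ggn")

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(state, out_dir / "checkpoint-final.ggn")
        (out_dir / "history.csv").write_text(state.history_csv())
    return state


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(state: TrainState, path: str | Path) -> None:
    """Single-archive checkpoint: config JSON + all network parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(state.config).items()}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps({"config": cfg, "step": state.step}))
        for name, module in [("generator", state.generator),
                             ("d_whole", state.d_whole),
                             ("d_roi", state.d_roi)]:
            buf = io.BytesIO()
            arrays = module.state_arrays()
            np.savez(buf, *arrays)
            zf.writestr(f"{name}.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> TrainState:
    with zipfile.ZipFile(Path(path)) as zf:
        meta = json.loads(zf.read("config.json"))
        cfg_dict = meta["config"]
        cfg_dict["adam_betas"] = tuple(cfg_dict["adam_betas"])
        config = GANConfig(**cfg_dict)
        gen = build_generator(config)
        d_whole = build_discriminator(config, "whole")
        d_roi = build_discriminator(config, "roi")
        for name, module in [("generator", gen), ("d_whole", d_whole),
                             ("d_roi", d_roi)]:
            with np.load(io.BytesIO(zf.read(f"{name}.npz"))) as npz:
                module.load_state_arrays([npz[k] for k in npz.files])
    return TrainState(step=meta["step"], config=config, generator=gen,
                      d_whole=d_whole, d_roi=d_roi)


def generate_synthetic(
    state_or_path: TrainState | str | Path,
    input_image: CTSlice,
    roi_box: Box,
) -> CTSlice:
    """Inference: fill the blanked ROI of ``input_image`` with the generator.

    With ``composite_output`` set in the config, pixels outside ``roi_box``
    are bit-identical to the input; only the ROI is synthesised.
    """
    state = (state_or_path if isinstance(state_or_path, TrainState)
             else load_checkpoint(state_or_path))
    config = state.config
    if input_image.shape != (config.image_size, config.image_size):
        raise ValueError(
            f"input is {input_image.shape} but checkpoint expects "
            f"{config.image_size}x{config.image_size}"
        )
    gen = state.generator
    gen.eval()
    try:
        x = nn.Tensor(input_image.pixels.astype(np.float32)[None, None])
        out = gen(x).data[0, 0].astype(np.float64)
    finally:
        gen.train()
    out = np.clip(out, 0.0, 1.0)
    if config.composite_output:
        mask = np.zeros(input_image.shape, dtype=bool)
        r0, c0, r1, c1 = roi_box
        mask[r0:r1, c0:c1] = True
        out = composite(out, input_image.pixels, mask)
    return CTSlice(out, spacing=input_image.spacing, normalized=True,
                   id=input_image.id + "-synth")
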