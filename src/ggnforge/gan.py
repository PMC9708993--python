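"""Generator, dual discriminators, and the composite inpainting loss.

The generator is a residual-block image-to-image network in the style of
the SRGAN generator but with no upsampling stage: it receives a normalised
slice whose nodule ROI has been blanked and must output a full slice of the
same size with the nodule filled in.  Two residual-network discriminators
judge realism -- one on the whole slice, one on the fixed-size ROI crop of
it -- and the generator objective is, for each of the two views,

    L = L_ssim + L_adversarial

where ``L_ssim = 1 - SSIM(generated, target)`` and ``L_adversarial`` is the
sum over the batch of ``-log D(G(x))``.  The total is the sum of the four
terms (SSIM + adversarial, each for whole image and ROI).

SSIM here defaults to the *global* form -- a single structural-similarity
index from whole-image means, variances and covariance -- with an 11x11
Gaussian-windowed average available as an option.  The non-standard
asymmetric variant of the index (denominator products of the squared
statistics rather than sums) is kept behind ``printed_form=True`` for
comparison; it is not the default because it is asymmetric and does not
equal 1 for identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .types import Box

__all__ = [
    "GANConfig", "LossBreakdown", "Generator", "Discriminator",
    "build_generator", "build_discriminator",
    "ssim", "ssim_loss", "adversarial_loss", "discriminator_loss",
    "total_generator_loss", "crop_roi", "composite",
    "SSIM_C1", "SSIM_C2",
]

# universal SSIM stabilising constants for dynamic range L = 1
SSIM_C1 = (0.01 * 1.0) ** 2
SSIM_C2 = (0.03 * 1.0) ** 2

_SCORE_EPS = 1e-6


@dataclass
class GANConfig:
    image_size: int = 512
    roi_size: int = 32
    n_res_blocks: int = 8
    base_channels: int = 32
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 4
    steps: int = 200
    seed: int = 0
    ssim_mode: str = "global"
    composite_output: bool = True
    adv_reduction: str = "sum"
    label_smoothing: bool = False
    checkpoint_interval: int = 0  # 0 = only final

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.roi_size > self.image_size:
            raise ValueError("roi_size cannot exceed image_size")
        if self.ssim_mode not in ("global", "windowed"):
            raise ValueError(f"unknown ssim_mode {self.ssim_mode!r}")
        if self.adv_reduction not in ("sum", "mean"):
            raise ValueError(f"unknown adv_reduction {self.adv_reduction!r}")


@dataclass
class LossBreakdown:
    """The four generator-objective terms and their exact sum."""

    l_ssim_whole: float
    l_adv_whole: float
    l_ssim_roi: float
    l_adv_roi: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = (self.l_ssim_whole + self.l_adv_whole
                      + self.l_ssim_roi + self.l_adv_roi)


# --------------------------------------------------------------------------
# SSIM
# --------------------------------------------------------------------------

def _ssim_global(x, y, c1: float, c2: float, printed_form: bool):
    """Structural-similarity expression valid for numpy arrays and autograd
    tensors alike (only +, -, *, /, mean are used)."""
    mu_x = x.mean()
    mu_y = y.mean()
    var_x = ((x - mu_x) ** 2).mean()
    var_y = ((y - mu_y) ** 2).mean()
    cov = ((x - mu_x) * (y - mu_y)).mean()
    if printed_form:
        num = (2.0 * mu_x * mu_y + c1) + (cov + c2)
        den = (mu_x ** 2 * mu_y ** 2 + c1) * (var_x * var_y + c2)
        return num / den
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)
    return num / den


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return (k / k.sum()).astype(np.float32)


def _ssim_windowed_t(x: nn.Tensor, y: nn.Tensor, c1: float, c2: float) -> nn.Tensor:
    """Mean SSIM over sliding 11x11 Gaussian windows (autograd tensors,
    NCHW with a single channel)."""
    k = _gaussian_kernel()
    w = nn.Tensor(k.reshape(1, 1, *k.shape))

    def filt(t: nn.Tensor) -> nn.Tensor:
        return nn.conv2d(t, w, stride=1, pad=0)

    mu_x, mu_y = filt(x), filt(y)
    sxx = filt(x * x) - mu_x * mu_x
    syy = filt(y * y) - mu_y * mu_y
    sxy = filt(x * y) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * sxy + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (sxx + syy + c2)
    return (num / den).mean()


def _as_nchw(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float32)
    if a.ndim == 2:
        return a[None, None]
    if a.ndim == 3:
        return a[:, None]
    return a


def ssim(x, y, c1: float = SSIM_C1, c2: float = SSIM_C2,
         mode: str = "global", printed_form: bool = False) -> float:
    """Structural similarity index of two same-shape images in [0, 1].

    ``mode='global'`` uses whole-image statistics; ``mode='windowed'``
    averages the index over 11x11 Gaussian windows.  Symmetric in (x, y)
    unless ``printed_form`` selects the non-standard asymmetric variant.
    """
    if c1 <= 0 or c2 <= 0:
        raise ValueError("SSIM constants must be positive")
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    if mode == "global":
        return float(_ssim_global(xa, ya, c1, c2, printed_form))
    if mode == "windowed":
        if printed_form:
            raise ValueError("printed_form is only defined for global mode")
        xt, yt = nn.Tensor(_as_nchw(xa)), nn.Tensor(_as_nchw(ya))
        return float(_ssim_windowed_t(xt, yt, c1, c2).data)
    raise ValueError(f"unknown mode {mode!r}")


def ssim_loss(x, y, c1: float = SSIM_C1, c2: float = SSIM_C2,
              mode: str = "global") -> float:
    """1 - SSIM; zero iff the structural-similarity index is 1."""
    return 1.0 - ssim(x, y, c1, c2, mode=mode)


def ssim_loss_t(x: nn.Tensor, y: nn.Tensor, mode: str = "global") -> nn.Tensor:
    """Differentiable 1 - SSIM for NCHW tensors, averaged over the batch."""
    if mode == "windowed":
        return 1.0 - _ssim_windowed_t(x, y, SSIM_C1, SSIM_C2)
    n = x.shape[0]
    acc = None
    for i in range(n):
        s = _ssim_global(x[i], y[i], SSIM_C1, SSIM_C2, printed_form=False)
        acc = s if acc is None else acc + s
    return 1.0 - acc * (1.0 / n)


# --------------------------------------------------------------------------
# Adversarial losses
# --------------------------------------------------------------------------

def _check_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("empty score list")
    if np.any(scores <= 0) or np.any(scores >= 1):
        raise ValueError("discriminator scores must lie strictly in (0, 1)")
    return scores


def adversarial_loss(d_scores, reduction: str = "sum") -> float:
    """Generator-side adversarial term: sum over the batch of -log D(G(x))."""
    scores = _check_scores(d_scores)
    total = float(-np.log(scores).sum())
    if reduction == "mean":
        return total / scores.size
    return total


def discriminator_loss(real_scores, fake_scores) -> float:
    """Binary cross-entropy for the discriminator:
    -sum log(real) - sum log(1 - fake)."""
    real = _check_scores(real_scores)
    fake = _check_scores(fake_scores)
    return float(-np.log(real).sum() - np.log(1.0 - fake).sum())


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------

def crop_roi(image, roi_box: Box):
    """Half-open sub-grid image[r0:r1, c0:c1] (last two axes for tensors)."""
    r0, c0, r1, c1 = roi_box
    if isinstance(image, nn.Tensor):
        h, w = image.shape[-2], image.shape[-1]
    else:
        image = np.asarray(image)
        h, w = image.shape[-2], image.shape[-1]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"roi_box {roi_box} out of bounds for {h}x{w}")
    if isinstance(image, nn.Tensor):
        return image[..., r0:r1, c0:c1]
    return image[..., r0:r1, c0:c1]


def composite(generated, target_input, roi_mask) -> np.ndarray:
    """Generated content inside the ROI, known input everywhere else."""
    generated = np.asarray(generated)
    target_input = np.asarray(target_input)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if generated.shape != target_input.shape or roi_mask.shape != generated.shape:
        raise ValueError("composite inputs must share one shape")
    return np.where(roi_mask, generated, target_input)


def total_generator_loss(
    generated: np.ndarray,
    target: np.ndarray,
    roi_box: Box,
    d_whole_score: float,
    d_roi_score: float,
    ssim_mode: str = "global",
    adv_reduction: str = "sum",
) -> LossBreakdown:
    """The four-term objective evaluated on numpy images (metric use)."""
    generated = np.asarray(generated)
    target = np.asarray(target)
    if generated.shape != target.shape:
        raise ValueError("generated/target shape mismatch")
    lsw = ssim_loss(generated, target, mode=ssim_mode)
    lsr = ssim_loss(crop_roi(generated, roi_box), crop_roi(target, roi_box),
                    mode=ssim_mode)
    law = adversarial_loss(np.atleast_1d(d_whole_score), reduction=adv_reduction)
    lar = adversarial_loss(np.atleast_1d(d_roi_score), reduction=adv_reduction)
    return LossBreakdown(l_ssim_whole=lsw, l_adv_whole=law,
                         l_ssim_roi=lsr, l_adv_roi=lar)


# --------------------------------------------------------------------------
# Networks
# --------------------------------------------------------------------------

class _ResBlockG(nn.Module):
    """(3x3 conv -> BN -> PReLU) x2 with identity skip (generator style)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(channels, channels, rng=rng)
        self.bn1 = nn.BatchNorm2d(channels)
        self.act1 = nn.PReLU()
        self.conv2 = nn.Conv2d(channels, channels, rng=rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        y = self.act1(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return x + y


class _ResBlockD(nn.Module):
    """Residual block with leaky activations (discriminator style)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(channels, channels, rng=rng)
        self.bn1 = nn.BatchNorm2d(channels)
        self.act = nn.LeakyReLU(0.2)
        self.conv2 = nn.Conv2d(channels, channels, rng=rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        y = self.act(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return self.act(x + y)


class Generator(nn.Module):
    """Residual image-to-image inpainting network with sigmoid output."""

    role = "generator"

    def __init__(self, config: GANConfig):
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        self.config = config
        self.head = nn.Conv2d(1, c, rng=rng)
        self.head_act = nn.PReLU()
        self.blocks = [_ResBlockG(c, rng) for _ in range(config.n_res_blocks)]
        self.post = nn.Conv2d(c, c, rng=rng)
        self.post_bn = nn.BatchNorm2d(c)
        self.tail = nn.Conv2d(c, 1, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[-1] != x.shape[-2]:
            raise ValueError("generator expects square inputs")
        h = self.head_act(self.head(x))
        y = h
        for block in self.blocks:
            y = block(y)
        y = self.post_bn(self.post(y)) + h  # long skip, SRGAN style
        return self.tail(y).sigmoid()


class Discriminator(nn.Module):
    """Residual classifier emitting one realism score strictly in (0, 1).

    Strided 3x3 convolutions halve the spatial extent between residual
    stages until the map is at most 4x4, then global average pooling and a
    dense layer produce the score.
    """

    def __init__(self, config: GANConfig, which: str):
        if which not in ("whole", "roi"):
            raise ValueError(f"which must be 'whole' or 'roi', got {which!r}")
        self.role = f"{which}_discriminator"
        self.input_size = config.image_size if which == "whole" else config.roi_size
        rng = np.random.default_rng(config.seed + (1 if which == "whole" else 2))
        c = config.base_channels
        self.head = nn.Conv2d(1, c, rng=rng)
        self.head_act = nn.LeakyReLU(0.2)
        stages: list[nn.Module] = []
        size = self.input_size
        ch = c
        while size > 4:
            stages.append(_ResBlockD(ch, rng))
            nxt = min(ch * 2, 4 * config.base_channels)
            down = nn.Sequential(
                nn.Conv2d(ch, nxt, stride=2, rng=rng),
                nn.BatchNorm2d(nxt),
                nn.LeakyReLU(0.2),
            )
            stages.append(down)
            ch = nxt
            size = (size + 1) // 2
        stages.append(_ResBlockD(ch, rng))
        self.stages = stages
        self.fc = nn.Dense(ch, 1, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[-2:] != (self.input_size, self.input_size):
            raise ValueError(
                f"{self.role} expects {self.input_size}x{self.input_size} input, "
                f"got {x.shape[-2]}x{x.shape[-1]}"
            )
        y = self.head_act(self.head(x))
        for stage in self.stages:
            y = stage(y)
        y = y.mean(axis=(2, 3))  # global average pool -> (N, C)
        score = self.fc(y).sigmoid()
        # squeeze strictly inside the open interval (0, 1)
        return score * (1.0 - 2 * _SCORE_EPS) + _SCORE_EPS


def build_generator(config: GANConfig) -> Generator:
    return Generator(config)


def build_discriminator(config: GANConfig, which: str) -> Discriminator:
    return Discriminator(config, which)
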