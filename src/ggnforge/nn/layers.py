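"""Network building blocks: convolution, batch norm, activations, dense.

Layers hold their parameters as autograd tensors; construction is seeded
through an explicit numpy Generator so identical (architecture, seed) gives
bit-identical initial parameters.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "PReLU", "LeakyReLU",
    "Dense", "Sigmoid", "Sequential",
]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    # -- state dict (plain numpy arrays, ordered by attribute traversal) --
    def state_arrays(self) -> list[np.ndarray]:
        out = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                out.extend([m.running_mean, m.running_var])
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        arrays = list(arrays)
        for p in self.parameters():
            a = arrays.pop(0)
            if a.shape != p.data.shape:
                raise ValueError("state shape mismatch")
            p.data = a.astype(np.float32).copy()
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = arrays.pop(0).astype(np.float32).copy()
                m.running_var = arrays.pop(0).astype(np.float32).copy()
        if arrays:
            raise ValueError("extra arrays in state")


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init
        self.weight = Tensor(rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(c))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class PReLU(Module):
    """Parametric rectified linear unit with one learnable slope."""

    def __init__(self, init: float = 0.25):
        self.alpha = Tensor(np.array([init]), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.relu() - self.alpha.reshape(1) * (-x).relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.relu() - self.slope * (-x).relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Dense(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias.reshape(1, -1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
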