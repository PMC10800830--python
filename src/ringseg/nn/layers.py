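"""Neural-network layers built on the autograd engine.

Covers what the transformer encoder / convolutional decoder needs: linear
projections, layer/batch normalization, multi-head self-attention, GELU
MLPs, 3x3 convolutions and 2x2 stride-2 transposed convolutions.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor


class Module:
    """Minimal container with parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def _children(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                yield from (v for v in value if isinstance(v, Module))

    def train(self, flag: bool = True):
        self.training = flag
        for child in self._children():
            child.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # state dict also carries non-trainable buffers (running BN statistics)
    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, np.ndarray):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name}")
                params[name].data[...] = value
            else:
                buffers[name][...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = math.sqrt(1.0 / fan_in)
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _param(rng, (n_in, n_out), n_in)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel with running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(c) - self.running_mean
            )
            self.running_var += self.momentum * (
                var.data.reshape(c) - self.running_var
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            xc = x - mu
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = xc / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng, padding: int = 0):
        super().__init__()
        self.weight = _param(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class ConvTranspose2x2(Module):
    """2x2, stride-2 transposed convolution: doubles spatial resolution."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.weight = _param(rng, (c_in, c_out, 2, 2), c_in * 4)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d_2x2(self.weight, self.bias)


class ConvBNReLU(Module):
    """3x3 convolution + batch norm + ReLU (same-padding)."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, 3, rng, padding=1)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class DeconvConvBNReLU(Module):
    """2x2 deconvolution followed by a 3x3 conv + batch norm + ReLU."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.up = ConvTranspose2x2(c_in, c_out, rng)
        self.block = ConvBNReLU(c_out, c_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.block(self.up(x))


class SelfAttention(Module):
    """Multi-head self-attention with separate Q/K/V projections."""

    def __init__(self, dim: int, n_heads: int, rng):
        super().__init__()
        if dim % n_heads:
            raise ValueError("embedding dim must be divisible by the head count")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def _split(self, x: Tensor, n: int, t: int) -> Tensor:
        return x.reshape(n, t, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        n, t, k = x.shape
        q = self._split(self.q(x), n, t)  # n, h, t, d
        key = self._split(self.k(x), n, t)
        v = self._split(self.v(x), n, t)
        scores = (q @ key.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, k)
        return self.proj(out)


class MLP(Module):
    """Two-layer perceptron with GELU, as used inside transformer blocks."""

    def __init__(self, dim: int, hidden: int, rng):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerBlock(Module):
    """Pre-norm transformer encoder block: LN -> MHSA -> LN -> MLP, residual."""

    def __init__(self, dim: int, n_heads: int, mlp_hidden: int, rng):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, mlp_hidden, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))
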