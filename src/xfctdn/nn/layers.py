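"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import hashlib

import numpy as np

from .autograd import Parameter, Tensor

__all__ = [
    "Module", "Linear", "Conv2d", "ConvTranspose2x2", "LayerNorm",
    "BatchNorm2d", "Mlp", "state_hash", "trunc_normal", "kaiming_normal",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples clipped to +-2 std (init for attention/MLP)."""
    return np.clip(rng.normal(0.0, std, size=shape), -2 * std, 2 * std)


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Base class: recursive parameter/buffer discovery, state dicts."""

    def __init__(self):
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    # -- traversal -----------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        self.training = True
        for _, c in self._children():
            c.train()

    def eval(self) -> None:
        self.training = False
        for _, c in self._children():
            c.eval()

    # -- state ---------------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters(prefix)}
        out.update(self._named_buffers(prefix))
        return out

    def _named_buffers(self, prefix: str = ""):
        out = {prefix + k: v.copy() for k, v in self._buffers.items()}
        for cname, child in self._children():
            out.update(child._named_buffers(prefix + cname + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = self._buffer_refs()
        missing = (set(params) | set(bufs)) - set(state)
        extra = set(state) - set(params) - set(bufs)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.data.shape} vs {state[name].shape}")
            p.data = np.array(state[name], dtype=np.float64)
        for name, (owner, key) in bufs.items():
            owner._buffers[key] = np.array(state[name], dtype=np.float64)

    def _buffer_refs(self, prefix: str = ""):
        out = {prefix + k: (self, k) for k in self._buffers}
        for cname, child in self._children():
            out.update(child._buffer_refs(prefix + cname + "."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def state_hash(module: Module) -> str:
    """Deterministic hash of all parameters and buffers (order-stable)."""
    h = hashlib.sha256()
    state = module.state_dict()
    for name in sorted(state):
        h.update(name.encode())
        h.update(np.ascontiguousarray(state[name]).tobytes())
    return h.hexdigest()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(kaiming_normal(rng, (out_ch, in_ch, kernel, kernel),
                                               fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution (the TConv upscaler)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(kaiming_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2x2(self.weight, self.bias)


class LayerNorm(Module):
    """Normalization over the last axis (token channel dim)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return xc * inv * self.gamma + self.beta


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, NCHW layout."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self._buffers["running_mean"] = np.zeros(channels)
        self._buffers["running_var"] = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self._buffers["running_mean"] = (
                (1 - self.momentum) * self._buffers["running_mean"]
                + self.momentum * mu.data.reshape(c))
            self._buffers["running_var"] = (
                (1 - self.momentum) * self._buffers["running_var"]
                + self.momentum * var.data.reshape(c))
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, c, 1, 1))
            xc = x - mu
            var = Tensor(self._buffers["running_var"].reshape(1, c, 1, 1))
        inv = (var + self.eps).pow(-0.5)
        return xc * inv * self.gamma.reshape(1, c, 1, 1) \
            + self.beta.reshape(1, c, 1, 1)


class Mlp(Module):
    """Two-layer GELU MLP used inside transformer blocks."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())
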