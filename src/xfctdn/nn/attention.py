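"""Shifted-window (Swin) attention blocks.

A Swin transformer block applies multi-head self-attention inside
non-overlapping ``window_size x window_size`` windows of the feature
map.  Alternating blocks shift the partition by half a window
(cyclically) so information propagates across window borders; attention
across the wrap-around seams is suppressed with an additive mask.

Plain windowed attention is used (no learned relative-position bias);
this keeps the parameterization minimal and is recorded in the model
config.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .layers import Linear, LayerNorm, Mlp, Module

__all__ = ["WindowAttention", "SwinBlock", "window_partition", "window_reverse"]


def window_partition(x: Tensor, ws: int) -> Tensor:
    """(N, C, H, W) -> (N * nWindows, ws*ws, C) token windows."""
    n, c, h, w = x.shape
    if h % ws or w % ws:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by window {ws}")
    t = x.reshape(n, c, h // ws, ws, w // ws, ws)
    t = t.transpose(0, 2, 4, 3, 5, 1)       # N, nh, nw, ws, ws, C
    return t.reshape(n * (h // ws) * (w // ws), ws * ws, c)


def window_reverse(t: Tensor, ws: int, n: int, c: int, h: int, w: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    x = t.reshape(n, h // ws, w // ws, ws, ws, c)
    x = x.transpose(0, 5, 1, 3, 2, 4)       # N, C, nh, ws, nw, ws
    return x.reshape(n, c, h, w)


def shift_attention_mask(h: int, w: int, ws: int, shift: int) -> np.ndarray:
    """Additive attention mask (nWindows, T, T) for a cyclic shift.

    Tokens belonging to different pre-shift regions inside the same
    post-shift window must not attend to each other; those entries get a
    large negative value.
    """
    img = np.zeros((h, w), dtype=np.int64)
    cnt = 0
    slices = (slice(0, -ws), slice(-ws, -shift), slice(-shift, None))
    for hs in slices:
        for wsl in slices:
            img[hs, wsl] = cnt
            cnt += 1
    img = np.roll(img, (-shift, -shift), axis=(0, 1))
    wins = img.reshape(h // ws, ws, w // ws, ws).transpose(0, 2, 1, 3)
    wins = wins.reshape(-1, ws * ws)
    diff = wins[:, :, None] != wins[:, None, :]
    return np.where(diff, -1e9, 0.0)


class WindowAttention(Module):
    """Multi-head self-attention over token windows."""

    def __init__(self, dim: int, head_dim: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.n_heads = max(1, dim // head_dim)
        self.head_dim = dim // self.n_heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.last_attn: np.ndarray | None = None  # inspection hook (tests)

    def forward(self, tokens: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b, t, c = tokens.shape
        qkv = self.qkv(tokens)                                   # (B, T, 3C)
        qkv = qkv.reshape(b, t, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)                       # 3, B, H, T, hd
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q * self.scale) @ k.transpose(0, 1, 3, 2)        # B, H, T, T
        if mask is not None:
            nw = mask.shape[0]
            m = np.broadcast_to(mask[None, :, None],
                                (b // nw, nw, self.n_heads, t, t))
            attn = attn + Tensor(m.reshape(b, self.n_heads, t, t))
        attn = attn.softmax(axis=-1)
        self.last_attn = attn.data
        out = attn @ v                                           # B, H, T, hd
        out = out.transpose(0, 2, 1, 3).reshape(b, t, c)
        return self.proj(out)


class SwinBlock(Module):
    """LN -> (shifted) window MSA -> +residual -> LN -> MLP -> +residual."""

    def __init__(self, dim: int, window_size: int, head_dim: int,
                 mlp_ratio: float, shift: int, rng: np.random.Generator):
        super().__init__()
        if window_size <= 0:
            raise ValueError("window_size must be positive")
        self.dim = dim
        self.ws = window_size
        self.shift = shift
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, head_dim, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(round(dim * mlp_ratio)), rng)
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}

    def _mask(self, h: int, w: int) -> np.ndarray | None:
        if self.shift == 0:
            return None
        key = (h, w)
        if key not in self._mask_cache:
            self._mask_cache[key] = shift_attention_mask(h, w, self.ws, self.shift)
        return self._mask_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        # tokens (N, H*W, C)
        tok = x.reshape(n, c, h * w).transpose(0, 2, 1)
        y = self.norm1(tok)
        ymap = y.transpose(0, 2, 1).reshape(n, c, h, w)
        if self.shift:
            ymap = ymap.roll((-self.shift, -self.shift), axes=(2, 3))
        wins = window_partition(ymap, self.ws)
        wins = self.attn(wins, self._mask(h, w))
        ymap = window_reverse(wins, self.ws, n, c, h, w)
        if self.shift:
            ymap = ymap.roll((self.shift, self.shift), axes=(2, 3))
        tok = tok + ymap.reshape(n, c, h * w).transpose(0, 2, 1)
        tok = tok + self.mlp(self.norm2(tok))
        return tok.transpose(0, 2, 1).reshape(n, c, h, w)
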