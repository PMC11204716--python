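"""Swin-Conv UNet denoiser.

The network is a 4-scale UNet whose basic unit is the swin-conv (SC)
block: the input feature map passes a 1x1 convolution, is split into
two channel halves, one half goes through a Swin transformer block
(non-local modeling), the other through a residual convolution block
(local modeling); the halves are concatenated, fused by a second 1x1
convolution and added back to the block input:

    x1, x2 = split(conv1x1(x))
    y1, y2 = SwinT(x1), RConv(x2)
    z      = conv1x1(concat(y1, y2)) + x

Downscaling uses 2x2 stride-2 convolutions (SConv), upscaling 2x2
transposed convolutions (TConv) with additive skip connections from the
matching scale.  Default channels per scale are 64/128/256/512 with
four SC blocks per scale; a ``tiny`` preset (16/32/64/128, one block
per scale, window 4) serves desk-scale experiments.  Within a run of
blocks the Swin shift alternates 0, w/2, 0, w/2.

Arbitrary input sizes are handled by reflect-padding up to the least
multiple of ``8 * window_size`` and cropping the output back.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (Conv2d, ConvTranspose2x2, Module, SwinBlock, Tensor,
                 concat)

__all__ = ["ModelConfig", "RConvBlock", "SCBlock", "SCUNet",
           "TINY_CONFIG", "FULL_CONFIG", "build_model",
           "save_checkpoint", "load_checkpoint", "count_parameters"]


@dataclass(frozen=True)
class ModelConfig:
    """SC-UNet hyperparameters.

    Relative-position bias is intentionally omitted from the window
    attention (plain windowed attention); all other defaults follow the
    published SCUNet configuration.
    """
    in_channels: int = 1
    scale_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_scale: int = 4
    window_size: int = 8
    head_dim: int = 32
    mlp_ratio: float = 4.0
    input_size_hint: tuple[int, int] = (256, 256)

    def __post_init__(self):
        if len(self.scale_channels) != 4:
            raise ValueError("exactly four scales are required")
        if any(c % 2 for c in self.scale_channels):
            raise ValueError("scale channels must be even (split into halves)")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.blocks_per_scale < 1:
            raise ValueError("blocks_per_scale must be >= 1")

    # -- analytic parameter count (pure function of the config) --------
    def parameter_count(self) -> int:
        def linear(i, o):
            return i * o + o

        def conv(i, o, k):
            return i * o * k * k + o

        def swin(dim):
            n = 2 * 2 * dim                       # two LayerNorms
            n += linear(dim, 3 * dim) + linear(dim, dim)
            hidden = int(round(dim * self.mlp_ratio))
            n += linear(dim, hidden) + linear(hidden, dim)
            return n

        def sc_block(dim):
            half = dim // 2
            return (conv(dim, dim, 1) + conv(dim, dim, 1)
                    + swin(half)
                    + conv(half, half, 3) + conv(half, half, 3))

        ch = self.scale_channels
        total = conv(self.in_channels, ch[0], 3)          # head
        for s in range(3):
            total += self.blocks_per_scale * sc_block(ch[s])
            total += conv(ch[s], ch[s + 1], 2)            # SConv down
        total += self.blocks_per_scale * sc_block(ch[3])  # bottleneck
        for s in (2, 1, 0):
            total += ch[s + 1] * ch[s] * 4 + ch[s]        # TConv up
            total += self.blocks_per_scale * sc_block(ch[s])
        total += conv(ch[0], self.in_channels, 3)         # tail
        return total


TINY_CONFIG = ModelConfig(scale_channels=(16, 32, 64, 128), blocks_per_scale=1,
                          window_size=4, input_size_hint=(64, 64))
FULL_CONFIG = ModelConfig()


class RConvBlock(Module):
    """Residual convolution block: x + conv3x3(relu(conv3x3(x)))."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(dim, dim, 3, rng, padding=1)
        self.conv2 = Conv2d(dim, dim, 3, rng, padding=1)
        self.use_relu = True     # test hook: disable to probe linearity

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(x)
        if self.use_relu:
            y = y.relu()
        return x + self.conv2(y)


class SCBlock(Module):
    """Swin-conv block (channel split between SwinT and RConv branches)."""

    def __init__(self, dim: int, window_size: int, head_dim: int,
                 mlp_ratio: float, shift: int, rng: np.random.Generator):
        super().__init__()
        if dim % 2:
            raise ValueError("SC block needs an even channel count")
        self.dim = dim
        half = dim // 2
        self.conv_in = Conv2d(dim, dim, 1, rng)
        self.swin = SwinBlock(half, window_size, head_dim, mlp_ratio, shift, rng)
        self.rconv = RConvBlock(half, rng)
        self.conv_out = Conv2d(dim, dim, 1, rng)
        # zero-initialized fusion: each SC block starts as the identity,
        # keeping activations bounded in the deep residual stack
        self.conv_out.weight.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.dim:
            raise ValueError(f"expected {self.dim} channels, got {x.shape[1]}")
        half = self.dim // 2
        t = self.conv_in(x)
        x1 = t[:, :half]
        x2 = t[:, half:]
        y1 = self.swin(x1)
        y2 = self.rconv(x2)
        return self.conv_out(concat([y1, y2], axis=1)) + x


def _shift_for(index: int, window_size: int) -> int:
    # blocks alternate shift 0, w/2, 0, w/2 within each scale
    return (window_size // 2) if index % 2 else 0


class SCUNet(Module):
    """The full 4-scale Swin-Conv UNet."""

    def __init__(self, config: ModelConfig = FULL_CONFIG, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 77)))
        ch = config.scale_channels
        bps = config.blocks_per_scale
        w = config.window_size

        def blocks(dim):
            return [SCBlock(dim, w, config.head_dim, config.mlp_ratio,
                            _shift_for(i, w), rng) for i in range(bps)]

        self.head = Conv2d(config.in_channels, ch[0], 3, rng, padding=1)
        self.enc0 = blocks(ch[0])
        self.down0 = Conv2d(ch[0], ch[1], 2, rng, stride=2)
        self.enc1 = blocks(ch[1])
        self.down1 = Conv2d(ch[1], ch[2], 2, rng, stride=2)
        self.enc2 = blocks(ch[2])
        self.down2 = Conv2d(ch[2], ch[3], 2, rng, stride=2)
        self.body = blocks(ch[3])
        self.up2 = ConvTranspose2x2(ch[3], ch[2], rng)
        self.dec2 = blocks(ch[2])
        self.up1 = ConvTranspose2x2(ch[2], ch[1], rng)
        self.dec1 = blocks(ch[1])
        self.up0 = ConvTranspose2x2(ch[1], ch[0], rng)
        self.dec0 = blocks(ch[0])
        self.tail = Conv2d(ch[0], config.in_channels, 3, rng, padding=1)

    # -- core forward on a padded tensor -------------------------------
    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError("expected (N, C_in, H, W) input")
        mult = 8 * self.config.window_size
        if x.shape[2] % mult or x.shape[3] % mult:
            raise ValueError(f"spatial dims must be multiples of {mult}; "
                             "use denoise() for arbitrary sizes")
        h = self.head(x)
        s0 = h
        for blk in self.enc0:
            s0 = blk(s0)
        s1 = self.down0(s0)
        for blk in self.enc1:
            s1 = blk(s1)
        s2 = self.down1(s1)
        for blk in self.enc2:
            s2 = blk(s2)
        b = self.down2(s2)
        for blk in self.body:
            b = blk(b)
        d2 = self.up2(b) + s2
        for blk in self.dec2:
            d2 = blk(d2)
        d1 = self.up1(d2) + s1
        for blk in self.dec1:
            d1 = blk(d1)
        d0 = self.up0(d1) + s0
        for blk in self.dec0:
            d0 = blk(d0)
        return self.tail(d0)

    # -- public API on plain arrays -------------------------------------
    def denoise(self, image: np.ndarray) -> np.ndarray:
        """Denoise a single-channel [0, 1] image of arbitrary size.

        The image is reflect-padded to the least multiple of
        ``8 * window_size`` and the output cropped back, so the result
        has exactly the input shape.
        """
        image = np.asarray(image, dtype=np.float64)
        squeeze = False
        if image.ndim == 2:
            image = image[None, None]
            squeeze = True
        if image.ndim != 4 or image.shape[1] != 1:
            raise ValueError("denoise expects a single-channel image")
        n, c, h, w = image.shape
        mult = 8 * self.config.window_size
        ph = (-h) % mult
        pw = (-w) % mult
        padded = np.pad(image, ((0, 0), (0, 0), (0, ph), (0, pw)),
                        mode="reflect") if (ph or pw) else image
        out = self.forward(Tensor(padded)).data[:, :, :h, :w]
        return out[0, 0] if squeeze else out


def build_model(preset: str = "tiny", seed: int = 0) -> SCUNet:
    """Construct an SC-UNet from a named preset (``tiny`` or ``full``)."""
    if preset == "tiny":
        return SCUNet(TINY_CONFIG, seed=seed)
    if preset == "full":
        return SCUNet(FULL_CONFIG, seed=seed)
    raise ValueError(f"unknown preset {preset!r}")


def count_parameters(model: Module) -> int:
    return sum(p.data.size for p in model.parameters())


# ---------------------------------------------------------------------------
# checkpoints: single-file zip with weights + config + training metadata
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SCUNet | Module, config: ModelConfig | None,
                    meta: dict | None = None) -> None:
    state = model.state_dict()
    buf = io.BytesIO()
    np.savez(buf, **state)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("weights.npz", buf.getvalue())
        if config is not None:
            zf.writestr("config.json", json.dumps(asdict(config)))
        zf.writestr("meta.json", json.dumps(meta or {}, sort_keys=True))


def load_checkpoint(path) -> tuple[SCUNet, ModelConfig, dict]:
    """Rebuild an SC-UNet (architecture + weights) from a checkpoint file."""
    with zipfile.ZipFile(path) as zf:
        cfg = json.loads(zf.read("config.json"))
        meta = json.loads(zf.read("meta.json"))
        npz = np.load(io.BytesIO(zf.read("weights.npz")))
        state = {k: npz[k] for k in npz.files}
    cfg["scale_channels"] = tuple(cfg["scale_channels"])
    cfg["input_size_hint"] = tuple(cfg["input_size_hint"])
    config = ModelConfig(**cfg)
    model = SCUNet(config)
    model.load_state_dict(state)
    return model, config, meta


def load_state_into(path, model: Module) -> dict:
    """Load checkpoint weights into an existing (matching) model."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        npz = np.load(io.BytesIO(zf.read("weights.npz")))
        model.load_state_dict({k: npz[k] for k in npz.files})
    return meta
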