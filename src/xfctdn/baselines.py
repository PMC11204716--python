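"""Classical and CNN baseline denoisers: NLM, simplified BM3D, DnCNN.

All baselines obey one interface: a [0, 1] single-channel image in, an
image of the same shape out.  NLM and BM3D are deterministic; DnCNN is
a residual CNN trained with the shared pipeline.

The BM3D here is a deliberately simplified two-stage variant (2-D DCT
per block, 1-D Haar across the matched stack, hard threshold at
2.7 sigma, inverse transform, weighted aggregation, optional Wiener
second stage); exact replication of reference BM3D binaries is a
non-goal, and an external implementation can be registered as a
plug-in for strict comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fftpack import dctn, idctn
from scipy.ndimage import uniform_filter

from .nn import BatchNorm2d, Conv2d, Module, Tensor

__all__ = [
    "NLMParams", "BM3DParams", "DnCNNConfig", "DnCNN",
    "nlm_denoise", "bm3d_denoise", "estimate_noise_sigma",
    "DENOISER_REGISTRY", "register_denoiser",
]


# ---------------------------------------------------------------------------
# non-local means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NLMParams:
    """patch_radius/search_radius in pixels; h is the weight bandwidth."""
    patch_radius: int = 2
    search_radius: int = 7
    h: float = 0.1

    def __post_init__(self):
        if self.patch_radius <= 0 or self.search_radius <= 0:
            raise ValueError("radii must be positive")
        if self.search_radius < self.patch_radius:
            raise ValueError("search_radius must be >= patch_radius")


def estimate_noise_sigma(image: np.ndarray) -> float:
    """Robust noise-std estimate: MAD of the finest wavelet HH band.

    Uses the Haar HH detail (diagonal differences of 2x2 cells), the
    standard Donoho estimator sigma = median(|d|) / 0.6745.
    """
    x = np.asarray(image, dtype=np.float64)
    h2 = (x.shape[0] // 2) * 2
    w2 = (x.shape[1] // 2) * 2
    x = x[:h2, :w2]
    hh = (x[0::2, 0::2] - x[0::2, 1::2] - x[1::2, 0::2] + x[1::2, 1::2]) / 2.0
    return float(np.median(np.abs(hh)) / 0.6745)


def default_nlm_params(image: np.ndarray) -> NLMParams:
    """Spec'd defaults: patch 2, search 7, h tied to the noise estimate."""
    sigma = max(estimate_noise_sigma(image), 1e-6)
    patch_radius = 2
    n_patch = (2 * patch_radius + 1) ** 2
    # bandwidth ~ expected patch SSD under pure noise
    return NLMParams(patch_radius=patch_radius, search_radius=7,
                     h=np.sqrt(2.0 * n_patch) * sigma)


def nlm_denoise(image: np.ndarray, params: NLMParams | None = None) -> np.ndarray:
    """Non-local means with Gaussian patch-similarity weights.

    out(i) = sum_j w(i,j) img(j) / sum_j w(i,j) over the search window,
    with w(i,j) = exp(-||P_i - P_j||^2 / h^2) on raw patches (sum of
    squared differences over the (2p+1)^2 patch).  Borders use reflect
    padding.
    """
    image = np.asarray(image, dtype=np.float64)
    if params is None:
        params = default_nlm_params(image)
    if params.h <= 0:
        raise ValueError("h must be positive")
    p, s = params.patch_radius, params.search_radius
    if min(image.shape) <= 2 * s + 1:
        raise ValueError("image too small for the search window")
    pad = s + p
    xp = np.pad(image, pad, mode="reflect")
    h, w = image.shape
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    n_patch = (2 * p + 1) ** 2
    # vectorized over search offsets
    base = xp[s:s + h + 2 * p, s:s + w + 2 * p]          # patch-padded center
    for dy in range(-s, s + 1):
        for dx in range(-s, s + 1):
            cand = xp[s + dy:s + dy + h + 2 * p, s + dx:s + dx + w + 2 * p]
            d2 = (base - cand) ** 2
            ssd = uniform_filter(d2, size=2 * p + 1)[p:p + h, p:p + w] * n_patch
            wgt = np.exp(-ssd / params.h ** 2)
            num += wgt * cand[p:p + h, p:p + w]
            den += wgt
    return num / den


# ---------------------------------------------------------------------------
# simplified BM3D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BM3DParams:
    block_size: int = 8
    max_group: int = 16
    match_threshold: float = 2.5       # mean-squared distance per pixel units
    sigma: float = 0.05
    stage: str = "hard"                # "hard" or "hard+wiener"
    ref_stride: int = 4
    cand_stride: int = 2

    def __post_init__(self):
        if self.block_size not in (4, 8):
            raise ValueError("block_size must be 4 or 8")
        if self.max_group & (self.max_group - 1):
            raise ValueError("max_group must be a power of two")
        if self.stage not in ("hard", "hard+wiener"):
            raise ValueError("stage must be 'hard' or 'hard+wiener'")


def _haar_1d(stack: np.ndarray) -> np.ndarray:
    """Orthonormal Haar transform along axis 0 (length power of two)."""
    out = stack.astype(np.float64).copy()
    n = out.shape[0]
    while n > 1:
        half = n // 2
        a = (out[0:n:2] + out[1:n:2]) / np.sqrt(2.0)
        d = (out[0:n:2] - out[1:n:2]) / np.sqrt(2.0)
        out[:half] = a
        out[half:n] = d
        n = half
    return out


def _ihaar_1d(coef: np.ndarray) -> np.ndarray:
    out = coef.astype(np.float64).copy()
    n = 1
    total = out.shape[0]
    while n < total:
        a = out[:n].copy()
        d = out[n:2 * n].copy()
        out[0:2 * n:2] = (a + d) / np.sqrt(2.0)
        out[1:2 * n:2] = (a - d) / np.sqrt(2.0)
        n *= 2
    return out


def _extract_blocks(image: np.ndarray, bs: int, stride: int):
    h, w = image.shape
    ys = list(range(0, h - bs + 1, stride))
    xs = list(range(0, w - bs + 1, stride))
    if ys[-1] != h - bs:
        ys.append(h - bs)
    if xs[-1] != w - bs:
        xs.append(w - bs)
    pos = [(y, x) for y in ys for x in xs]
    blocks = np.stack([image[y:y + bs, x:x + bs] for y, x in pos])
    return pos, blocks


def match_blocks(image: np.ndarray, ref_pos: tuple[int, int],
                 params: BM3DParams) -> list[tuple[int, int]]:
    """Positions of the <= max_group candidates most similar to the block
    at ``ref_pos`` (mean-squared L2 distance below match_threshold), the
    reference itself first.  Group size is trimmed to a power of two."""
    bs = params.block_size
    ref = image[ref_pos[0]:ref_pos[0] + bs, ref_pos[1]:ref_pos[1] + bs]
    pos, blocks = _extract_blocks(image, bs, params.cand_stride)
    d = np.mean((blocks - ref) ** 2, axis=(1, 2))
    order = np.argsort(d, kind="stable")
    sel = [pos[i] for i in order
           if d[i] <= params.match_threshold][:params.max_group]
    if ref_pos in sel:
        sel.remove(ref_pos)
    sel = [ref_pos] + sel
    k = 1
    while k * 2 <= len(sel):
        k *= 2
    return sel[:k]


def _collaborative_filter(image: np.ndarray, params: BM3DParams,
                          pilot: np.ndarray | None = None
                          ) -> np.ndarray:
    bs = params.block_size
    h, w = image.shape
    acc = np.zeros_like(image)
    wacc = np.zeros_like(image)
    match_src = pilot if pilot is not None else image
    ys = list(range(0, h - bs + 1, params.ref_stride))
    xs = list(range(0, w - bs + 1, params.ref_stride))
    if ys[-1] != h - bs:
        ys.append(h - bs)
    if xs[-1] != w - bs:
        xs.append(w - bs)
    thr = 2.7 * params.sigma
    for y in ys:
        for x in xs:
            group_pos = match_blocks(match_src, (y, x), params)
            stack = np.stack([image[r:r + bs, c:c + bs]
                              for r, c in group_pos])
            spec = dctn(stack, axes=(1, 2), norm="ortho")
            spec = _haar_1d(spec)
            if pilot is None:
                keep = np.abs(spec) > thr
                keep[0, 0, 0] = True            # always keep group DC
                n_kept = int(keep.sum())
                spec = spec * keep
                weight = 1.0 / (1.0 + n_kept)
            else:
                pstack = np.stack([pilot[r:r + bs, c:c + bs]
                                   for r, c in group_pos])
                pspec = _haar_1d(dctn(pstack, axes=(1, 2), norm="ortho"))
                shrink = pspec ** 2 / (pspec ** 2 + params.sigma ** 2)
                spec = spec * shrink
                weight = 1.0 / (1.0 + float(np.sum(shrink ** 2)))
            est = idctn(_ihaar_1d(spec), axes=(1, 2), norm="ortho")
            for g, (r, c) in enumerate(group_pos):
                acc[r:r + bs, c:c + bs] += weight * est[g]
                wacc[r:r + bs, c:c + bs] += weight
    wacc[wacc == 0] = 1.0
    return acc / wacc


def bm3d_denoise(image: np.ndarray, params: BM3DParams | None = None
                 ) -> np.ndarray:
    """Simplified BM3D: block matching + collaborative transform filtering."""
    image = np.asarray(image, dtype=np.float64)
    params = params or BM3DParams(sigma=max(estimate_noise_sigma(image), 1e-6))
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    if params.block_size > min(image.shape):
        raise ValueError("block_size larger than image")
    est = _collaborative_filter(image, params)
    if params.stage == "hard+wiener":
        est = _collaborative_filter(image, params, pilot=est)
    return est


# ---------------------------------------------------------------------------
# DnCNN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DnCNNConfig:
    depth: int = 17
    channels: int = 64

    def __post_init__(self):
        if self.depth < 3:
            raise ValueError("depth must be >= 3")


class DnCNN(Module):
    """Residual denoising CNN: predicts the noise, returns y - v_hat.

    First layer conv+ReLU, middle layers conv+BatchNorm+ReLU, last layer
    a plain conv producing the noise estimate.
    """

    def __init__(self, config: DnCNNConfig = DnCNNConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 99)))
        c = config.channels
        self.first = Conv2d(1, c, 3, rng, padding=1)
        self.mid_convs = [Conv2d(c, c, 3, rng, padding=1, bias=False)
                          for _ in range(config.depth - 2)]
        self.mid_norms = [BatchNorm2d(c) for _ in range(config.depth - 2)]
        self.last = Conv2d(c, 1, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("DnCNN expects (N, 1, H, W) input")
        y = self.first(x).relu()
        for conv, norm in zip(self.mid_convs, self.mid_norms):
            y = norm(conv(y)).relu()
        v = self.last(y)
        return x - v

    def denoise(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        squeeze = image.ndim == 2
        if squeeze:
            image = image[None, None]
        out = self.forward(Tensor(image)).data
        return out[0, 0] if squeeze else out


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _identity(image, checkpoint=None):
    return np.asarray(image, dtype=np.float64)


def _nlm(image, checkpoint=None):
    return nlm_denoise(image)


def _bm3d(image, checkpoint=None):
    return bm3d_denoise(image)


#: name -> callable(image, checkpoint) -> image.  Learned methods are
#: registered by the bench module once a checkpoint is supplied;
#: external plug-ins (e.g. a reference BM3D/BM4D) may register here too.
DENOISER_REGISTRY: dict = {
    "identity": _identity,
    "nlm": _nlm,
    "bm3d": _bm3d,
}


def register_denoiser(name: str, fn) -> None:
    DENOISER_REGISTRY[name] = fn
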