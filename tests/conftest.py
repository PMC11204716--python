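"""Shared fixtures and independent oracle implementations.

Oracles here are deliberately naive (loops, dense linear algebra) and
never call the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from xfctdn.phantom import (ImagePair, PairMeta, build_dataset, child_rng,
                            random_phantom_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """5 phantoms x full grid x 4 rotations = 180 pairs at 64x64."""
    specs = [random_phantom_spec((64, 64), child_rng(7, 10, i))
             for i in range(5)]
    return build_dataset(specs, seed=7)


def make_pair(rng: np.random.Generator, size: int = 64,
              level: float = 0.75, bw: float = 0.5) -> ImagePair:
    clean = rng.random((size, size))
    noisy = np.clip(clean * (1 - level)
                    + rng.normal(0, 0.05, clean.shape), 0, 1)
    return ImagePair(noisy=noisy, clean=clean,
                     meta=PairMeta(noise_level=level, bin_width_keV=bw,
                                   augmentation_tag="r0", phantom_id=0))


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def psnr_oracle(ref: np.ndarray, test: np.ndarray, data_range: float) -> float:
    """Direct MSE-then-log evaluation of the PSNR formula."""
    err = 0.0
    n = 0
    for a, b in zip(ref.ravel(), test.ravel()):
        err += (float(a) - float(b)) ** 2
        n += 1
    mse = err / n
    return math.inf if mse == 0 else 10.0 * math.log10(data_range ** 2 / mse)


def ssim_oracle(ref: np.ndarray, test: np.ndarray, data_range: float,
                size: int = 11, sigma: float = 1.5,
                k1: float = 0.01, k2: float = 0.03) -> float:
    """Per-window sliding evaluation of the SSIM formula (brute force)."""
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    w = np.outer(g, g)
    w /= w.sum()
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    h, wd = ref.shape
    vals = []
    for i in range(h - size + 1):
        for j in range(wd - size + 1):
            px = ref[i:i + size, j:j + size].astype(float)
            py = test[i:i + size, j:j + size].astype(float)
            mx = (w * px).sum()
            my = (w * py).sum()
            vx = (w * px * px).sum() - mx * mx
            vy = (w * py * py).sum() - my * my
            vxy = (w * px * py).sum() - mx * my
            vals.append(((2 * mx * my + c1) * (2 * vxy + c2))
                        / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def nlm_oracle(image: np.ndarray, patch_radius: int, search_radius: int,
               h: float) -> np.ndarray:
    """Quadruple-loop non-local means with reflect padding."""
    p, s = patch_radius, search_radius
    pad = s + p
    xp = np.pad(image, pad, mode="reflect")
    hgt, wdt = image.shape
    out = np.zeros_like(image, dtype=float)
    for i in range(hgt):
        for j in range(wdt):
            ci, cj = i + pad, j + pad
            pref = xp[ci - p:ci + p + 1, cj - p:cj + p + 1]
            num = 0.0
            den = 0.0
            for di in range(-s, s + 1):
                for dj in range(-s, s + 1):
                    ni, nj = ci + di, cj + dj
                    pcand = xp[ni - p:ni + p + 1, nj - p:nj + p + 1]
                    d2 = float(((pref - pcand) ** 2).sum())
                    wgt = math.exp(-d2 / h ** 2)
                    num += wgt * xp[ni, nj]
                    den += wgt
            out[i, j] = num / den
    return out


def dense_attention_oracle(tokens: np.ndarray, wq, bq, wk, bk, wv, bv,
                           wp, bp, n_heads: int) -> np.ndarray:
    """Full self-attention computed directly from Q, K, V matrices."""
    t, c = tokens.shape
    hd = c // n_heads
    q = tokens @ wq + bq
    k = tokens @ wk + bk
    v = tokens @ wv + bv
    out = np.zeros((t, c))
    for hh in range(n_heads):
        sl = slice(hh * hd, (hh + 1) * hd)
        qa, ka, va = q[:, sl], k[:, sl], v[:, sl]
        logits = qa @ ka.T / math.sqrt(hd)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        attn = e / e.sum(axis=1, keepdims=True)
        out[:, sl] = attn @ va
    return out @ wp + bp


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar f with respect to array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
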