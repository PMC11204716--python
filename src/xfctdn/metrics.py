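"""Image-fidelity metrics: PSNR and SSIM.

PSNR is the standard ``10 log10(R^2 / MSE)`` in dB.  SSIM follows the
Wang et al. local-statistics form: an 11x11 Gaussian window (sigma 1.5)
slides over the image (valid positions only), local weighted means,
variances and covariance are combined per window as

    [(2 mu_x mu_y + C1)(2 sigma_xy + C2)] /
    [(mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)]

with C1 = (K1 R)^2, C2 = (K2 R)^2, and the mean over windows is
reported.  Constants K1 = 0.01, K2 = 0.03 and the window are the
de-facto standard; they are recorded in :class:`GaussianWindowSpec` so
benchmark reports are self-describing.

A differentiable SSIM (:func:`ssim_t`) on autograd tensors backs the
shape-aware compound training loss; it evaluates the identical formula,
so the scalar :func:`ssim` is its reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .nn.autograd import Tensor

__all__ = ["GaussianWindowSpec", "MetricRecord", "psnr", "ssim", "ssim_t",
           "gaussian_window"]


@dataclass(frozen=True)
class GaussianWindowSpec:
    """SSIM window: size x size Gaussian weights with given sigma."""
    size: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03


@dataclass(frozen=True)
class MetricRecord:
    """One (reference, test) comparison."""
    psnr_db: float
    ssim: float
    data_range: float


def gaussian_window(spec: GaussianWindowSpec) -> np.ndarray:
    """Normalized 2-D Gaussian weight window (sums to 1)."""
    half = (spec.size - 1) / 2.0
    ax = np.arange(spec.size) - half
    g = np.exp(-(ax ** 2) / (2.0 * spec.sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


def psnr(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = np.mean((ref - test) ** 2)
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range ** 2 / mse)


def _ssim_maps(ref: np.ndarray, test: np.ndarray, data_range: float,
               window: GaussianWindowSpec) -> np.ndarray:
    w = gaussian_window(window)
    c1 = (window.k1 * data_range) ** 2
    c2 = (window.k2 * data_range) ** 2
    mux = convolve2d(ref, w, mode="valid")
    muy = convolve2d(test, w, mode="valid")
    sxx = convolve2d(ref * ref, w, mode="valid") - mux * mux
    syy = convolve2d(test * test, w, mode="valid") - muy * muy
    sxy = convolve2d(ref * test, w, mode="valid") - mux * muy
    num = (2 * mux * muy + c1) * (2 * sxy + c2)
    den = (mux ** 2 + muy ** 2 + c1) * (sxx + syy + c2)
    return num / den


def ssim(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0,
         window: GaussianWindowSpec = GaussianWindowSpec()) -> float:
    """Mean structural similarity over all fully interior windows."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if min(ref.shape) < window.size:
        raise ValueError(f"image {ref.shape} smaller than SSIM window "
                         f"({window.size})")
    return float(np.mean(_ssim_maps(ref, test, data_range, window)))


def ssim_t(pred: Tensor, target: np.ndarray, data_range: float = 1.0,
           window: GaussianWindowSpec = GaussianWindowSpec()) -> Tensor:
    """Differentiable SSIM of a (N, 1, H, W) prediction against a target.

    Returns the scalar mean SSIM over windows and batch as a Tensor.
    The target is a constant (no gradient).
    """
    n, c, h, w_ = pred.shape
    if c != 1:
        raise ValueError("ssim_t expects single-channel input")
    if min(h, w_) < window.size:
        raise ValueError("image smaller than SSIM window")
    wk = gaussian_window(window)
    kern = Tensor(wk[None, None])
    c1 = (window.k1 * data_range) ** 2
    c2 = (window.k2 * data_range) ** 2
    tgt = Tensor(np.asarray(target, dtype=np.float64).reshape(n, 1, h, w_))
    mux = pred.conv2d(kern)
    muy = tgt.conv2d(kern)
    sxx = (pred * pred).conv2d(kern) - mux * mux
    syy = (tgt * tgt).conv2d(kern) - muy * muy
    sxy = (pred * tgt).conv2d(kern) - mux * muy
    num = (2.0 * mux * muy + c1) * (2.0 * sxy + c2)
    den = (mux * mux + muy * muy + c1) * (sxx + syy + c2)
    return (num / den).mean()
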