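"""Losses and the optimization / fine-tuning protocol.

Training minimizes a compound loss with Adam: the learning rate starts
at 1e-4 and decays by a factor 0.9 per epoch over 40 epochs, batch
size 2.  The multi-noise-level protocol trains first at the 25% noise
level and then fine-tunes separate checkpoints for the other levels.

The compound loss is a shape-aware extension of plain L1:

    L = L1 + alpha * (1 - SSIM(pred, target))
          + beta * mean(W * |pred - target|)

where W is the target's gradient-magnitude map normalized to mean 1
(uniform for a constant target), so edges of the Gd inserts receive
larger weight than flat water/background regions.  alpha = beta = 0
reduces it to plain L1.  The exact compound-loss formula of the source
this design follows is an interpretation, recorded in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import psnr, ssim, ssim_t
from .nn import Adam, Module, Tensor, state_hash
from .phantom import ImagePair, child_rng
from .scunet import load_state_into, save_checkpoint

__all__ = ["LossSpec", "TrainConfig", "History", "l1_loss", "compound_loss",
           "shape_weight_map", "train_denoiser", "lr_schedule"]


@dataclass(frozen=True)
class LossSpec:
    alpha_ssim: float = 0.5
    beta_shape: float = 1.0

    def __post_init__(self):
        if self.alpha_ssim < 0 or self.beta_shape < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 1e-4
    decay: float = 0.9
    epochs: int = 40
    batch_size: int = 2
    loss: LossSpec = LossSpec()
    seed: int = 0
    finetune_from: str | None = None

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must lie in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    init_hash: str = ""
    best_epoch: int = -1


def lr_schedule(config: TrainConfig, epoch: int) -> float:
    """lr at epoch e (0-based): lr0 * decay**e."""
    return config.lr0 * config.decay ** epoch


def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute difference."""
    t = np.asarray(target, dtype=np.float64)
    if pred.shape != t.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {t.shape}")
    return (pred - Tensor(t)).abs().mean()


def shape_weight_map(target: np.ndarray) -> np.ndarray:
    """Gradient-magnitude weight map of the target, normalized to mean 1.

    Central differences via np.gradient; a constant target yields the
    uniform map (all ones).
    """
    t = np.asarray(target, dtype=np.float64)
    gy, gx = np.gradient(t)
    mag = np.hypot(gy, gx)
    m = mag.mean()
    if m == 0:
        return np.ones_like(t)
    return mag / m


def compound_loss(pred: Tensor, target: np.ndarray,
                  spec: LossSpec = LossSpec()) -> Tensor:
    """L1 + alpha*(1 - SSIM) + beta*mean(W * |pred - target|).

    ``pred`` is a (N, 1, H, W) tensor (or any shape when alpha is 0);
    the SSIM term requires the 4-D layout.
    """
    t = np.asarray(target, dtype=np.float64)
    loss = l1_loss(pred, t)
    if spec.alpha_ssim > 0:
        loss = loss + spec.alpha_ssim * (1.0 - ssim_t(pred, t))
    if spec.beta_shape > 0:
        if t.ndim == 4:
            w = np.stack([[shape_weight_map(t[n, 0])] for n in range(t.shape[0])])
        else:
            w = shape_weight_map(t)
        weighted = (Tensor(w) * (pred - Tensor(t)).abs()).mean()
        loss = loss + spec.beta_shape * weighted
    return loss


def _batch(pairs: Sequence[ImagePair], idx: np.ndarray):
    noisy = np.stack([pairs[i].noisy for i in idx])[:, None]
    clean = np.stack([pairs[i].clean for i in idx])[:, None]
    return noisy, clean


def _validate(model, val_pairs: Sequence[ImagePair]) -> tuple[float, float]:
    ps, ss = [], []
    for pair in val_pairs:
        out = np.clip(model.denoise(pair.noisy), 0.0, 1.0)
        p = psnr(pair.clean, out)
        if np.isfinite(p):
            ps.append(p)
        ss.append(ssim(pair.clean, out))
    return (float(np.mean(ps)) if ps else float("inf"),
            float(np.mean(ss)))


def train_denoiser(model: Module, train_pairs: Sequence[ImagePair],
                   val_pairs: Sequence[ImagePair],
                   config: TrainConfig,
                   checkpoint_out: str | None = None,
                   model_config=None,
                   progress: bool = False) -> tuple[Module, History]:
    """Adam training loop with per-epoch lr decay and best-PSNR checkpointing.

    When ``config.finetune_from`` is set, weights are initialized from
    that checkpoint (never re-initialized: the parameter hash before the
    first step equals the checkpoint's).  The model is returned with the
    best-validation-PSNR weights restored; ``checkpoint_out`` (if given)
    receives the same weights.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    if config.finetune_from is not None:
        load_state_into(config.finetune_from, model)
    hist = History(init_hash=state_hash(model))

    opt = Adam(model.parameters(), lr=config.lr0)
    n = len(train_pairs)
    best_psnr = -np.inf
    best_state = model.state_dict()
    iterator = range(config.epochs)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="epochs")
    for epoch in iterator:
        opt.lr = lr_schedule(config, epoch)
        order = child_rng(config.seed, 3, epoch).permutation(n)
        model.train()
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            noisy, clean = _batch(train_pairs, idx)
            pred = model(Tensor(noisy))
            loss = compound_loss(pred, clean, config.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        model.eval()
        if val_pairs:
            vp, vs = _validate(model, val_pairs)
        else:
            vp, vs = float("nan"), float("nan")
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_psnr.append(vp)
        hist.val_ssim.append(vs)
        hist.lr.append(opt.lr)
        score = vp if val_pairs else -hist.train_loss[-1]
        if score > best_psnr:
            best_psnr = score
            best_state = model.state_dict()
            hist.best_epoch = epoch
    model.load_state_dict(best_state)
    model.eval()
    if checkpoint_out is not None:
        save_checkpoint(checkpoint_out, model, model_config,
                        meta={"epochs": config.epochs, "seed": config.seed,
                              "loss": {"alpha_ssim": config.loss.alpha_ssim,
                                       "beta_shape": config.loss.beta_shape},
                              "best_epoch": hist.best_epoch})
    return model, hist
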