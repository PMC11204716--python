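"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the operator set needed by the denoising
networks in this package: broadcast arithmetic, batched matmul, 2-D
convolution (im2col), 2x2 stride-2 transposed convolution, window
reshuffling primitives (reshape / transpose / slice / concat / roll),
softmax, GELU/ReLU and reductions.  Everything is float64; gradients are
accumulated into ``Tensor.grad`` by a topological backward sweep.

Design notes
------------
* A ``Tensor`` wraps an ``np.ndarray`` plus a closure that, given the
  output gradient, accumulates into its parents.  Graphs are built
  eagerly on every op; at the problem sizes this package targets the
  bookkeeping cost is negligible.
* Backward traversal is iterative (explicit stack) so deep sequential
  networks cannot hit the Python recursion limit.
* Broadcasting follows NumPy semantics; ``_unbroadcast`` sums gradients
  back to the parent shape.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with reverse-mode gradient support."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run the backward sweep seeding this tensor's gradient."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological order
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---------------- arithmetic --------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)

        def bw(g, a=self, b=other):
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(g, b.shape))

        return self._result(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g, a=self):
            a._accumulate(-g)

        return self._result(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)

        def bw(g, a=self, b=other):
            a._accumulate(_unbroadcast(g * b.data, a.shape))
            b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._result(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)

        def bw(g, a=self, b=other):
            a._accumulate(_unbroadcast(g / b.data, a.shape))
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._result(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other) -> "Tensor":
        return self._coerce(other) / self

    def pow(self, p: float) -> "Tensor":
        def bw(g, a=self):
            a._accumulate(g * p * a.data ** (p - 1))

        return self._result(self.data ** p, (self,), bw)

    __pow__ = pow

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            a._accumulate(g * o)

        return self._result(out_data, (self,), bw)

    def abs(self) -> "Tensor":
        def bw(g, a=self):
            a._accumulate(g * np.sign(a.data))

        return self._result(np.abs(self.data), (self,), bw)

    # ---------------- activations -------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g, a=self, m=mask):
            a._accumulate(g * m)

        return self._result(self.data * mask, (self,), bw)

    def gelu(self) -> "Tensor":
        # exact form: 0.5 x (1 + erf(x / sqrt(2)))
        from scipy.special import erf

        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def bw(g, a=self, c=cdf, p=pdf, xx=x):
            a._accumulate(g * (c + xx * p))

        return self._result(x * cdf, (self,), bw)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - np.max(self.data, axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g, a=self, sm=s, ax=axis):
            dot = np.sum(g * sm, axis=ax, keepdims=True)
            a._accumulate(sm * (g - dot))

        return self._result(s, (self,), bw)

    # ---------------- reductions --------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g, a=self, ax=axis, kd=keepdims):
            gg = np.asarray(g)
            if ax is not None and not kd:
                gg = np.expand_dims(gg, ax)
            a._accumulate(np.broadcast_to(gg, a.shape))

        return self._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))

        def bw(g, a=self, ax=axis, kd=keepdims, nn=n):
            gg = np.asarray(g) / nn
            if ax is not None and not kd:
                gg = np.expand_dims(gg, ax)
            a._accumulate(np.broadcast_to(gg, a.shape))

        return self._result(self.data.mean(axis=axis, keepdims=keepdims), (self,), bw)

    # ---------------- shape ops ---------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g, a=self):
            a._accumulate(g.reshape(a.shape))

        return self._result(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g, a=self, iv=inv):
            a._accumulate(g.transpose(iv))

        return self._result(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx) -> "Tensor":
        def bw(g, a=self, ix=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, ix, g)
            a._accumulate(full)

        return self._result(self.data[idx], (self,), bw)

    def roll(self, shifts, axes) -> "Tensor":
        def bw(g, a=self, sh=shifts, ax=axes):
            neg = tuple(-s for s in sh) if isinstance(sh, (tuple, list)) else -sh
            a._accumulate(np.roll(g, neg, axis=ax))

        return self._result(np.roll(self.data, shifts, axis=axes), (self,), bw)

    def pad2d(self, pad: int) -> "Tensor":
        """Zero-pad the two trailing (spatial) axes symmetrically."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]

        def bw(g, a=self, p=pad):
            a._accumulate(g[..., p:-p, p:-p])

        return self._result(np.pad(self.data, width), (self,), bw)

    # ---------------- matmul ------------------------------------------
    def matmul(self, other) -> "Tensor":
        other = self._coerce(other)

        def bw(g, a=self, b=other):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            a._accumulate(_unbroadcast(ga, a.shape))
            b._accumulate(_unbroadcast(gb, b.shape))

        return self._result(np.matmul(self.data, other.data), (self, other), bw)

    __matmul__ = matmul

    # ---------------- convolution -------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D convolution, NCHW layout, zero padding.

        weight: (OC, C, kh, kw); bias: (OC,) or None.
        """
        x = self.data
        w = weight.data
        n, c, h, wd = x.shape
        oc, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"channel mismatch: input {c}, weight {c2}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        oh = (h + 2 * padding - kh) // stride + 1
        ow = (wd + 2 * padding - kw) // stride + 1
        # cols: (N, OH, OW, C, kh, kw)
        view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        view = view[:, :, ::stride, ::stride]          # (N, C, OH, OW, kh, kw)
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
        wmat = w.reshape(oc, c * kh * kw)
        out = cols @ wmat.T                            # (N, OH*OW, OC)
        out = out.transpose(0, 2, 1).reshape(n, oc, oh, ow)
        if bias is not None:
            out = out + bias.data.reshape(1, oc, 1, 1)

        def bw(g, a=self, wt=weight, bt=bias, cl=cols):
            gmat = g.reshape(n, oc, oh * ow).transpose(0, 2, 1)   # (N, OH*OW, OC)
            gw = np.matmul(gmat.transpose(0, 2, 1), cl).sum(axis=0)
            wt._accumulate(gw.reshape(oc, c, kh, kw))
            if bt is not None:
                bt._accumulate(g.sum(axis=(0, 2, 3)))
            if a.requires_grad:
                gcols = gmat @ wmat                                # (N, OH*OW, C*kh*kw)
                gcols = gcols.reshape(n, oh, ow, c, kh, kw)
                gxp = np.zeros((n, c, h + 2 * padding, wd + 2 * padding))
                for ai in range(kh):
                    for bi in range(kw):
                        gxp[:, :, ai:ai + stride * oh:stride,
                            bi:bi + stride * ow:stride] += \
                            gcols[:, :, :, :, ai, bi].transpose(0, 3, 1, 2)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                a._accumulate(gxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._result(out, parents, bw)

    def conv_transpose2x2(self, weight: "Tensor",
                          bias: "Tensor | None" = None) -> "Tensor":
        """2x2 stride-2 transposed convolution (upscaling).

        weight: (C_in, C_out, 2, 2). Output spatial dims are doubled.
        """
        x = self.data
        w = weight.data
        n, c, h, wd = x.shape
        c2, oc, kh, kw = w.shape
        if c != c2 or (kh, kw) != (2, 2):
            raise ValueError("conv_transpose2x2 expects weight (C_in, C_out, 2, 2)")
        t = np.tensordot(x, w, axes=([1], [0]))      # (N, H, W, OC, 2, 2)
        t = t.transpose(0, 3, 1, 4, 2, 5)            # N, OC, H, a, W, b
        out = np.ascontiguousarray(t).reshape(n, oc, 2 * h, 2 * wd)
        if bias is not None:
            out = out + bias.data.reshape(1, oc, 1, 1)

        def bw(g, a=self, wt=weight, bt=bias):
            gt = g.reshape(n, oc, h, 2, wd, 2)       # N, OC, H, a, W, b
            # dW: sum over N, H, W -> (C, OC, 2, 2)
            wt._accumulate(np.tensordot(x, gt, axes=([0, 2, 3], [0, 2, 4])))
            if bt is not None:
                bt._accumulate(g.sum(axis=(0, 2, 3)))
            if a.requires_grad:
                dx = np.tensordot(gt, wt.data, axes=([1, 3, 5], [1, 2, 3]))
                a._accumulate(dx.transpose(0, 3, 1, 2))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._result(out, parents, bw)


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient support."""
    ts = list(tensors)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g, parts=ts, sp=splits, ax=axis):
        for part, gpart in zip(parts, np.split(g, sp, axis=ax)):
            part._accumulate(gpart)

    out = Tensor(np.concatenate([t.data for t in ts], axis=axis))
    if any(t.requires_grad for t in ts):
        out.requires_grad = True
        out._parents = tuple(ts)
        out._backward = bw
    return out
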