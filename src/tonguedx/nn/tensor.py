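"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small convolutional networks (nested-skip U-Nets for tongue
segmentation, a residual backbone for deep feature extraction) on CPU.  This
module provides the tape: a :class:`Tensor` wrapping a float32 ndarray plus the
closure needed to push gradients to its parents.  Only the operations those
networks need are implemented; convolutions lower to im2col + BLAS matmul so
desk-scale training stays fast.

Gradients are retained on every node (not just leaves) because Grad-CAM needs
the gradient of a class logit with respect to an intermediate feature map.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def _lift(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # -- reductions & shaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.reshape(self.shape))
        return out

    # -- elementwise nonlinearities --------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * s * (1.0 - s))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.data)
        return out

    # -- spatial operations (NCHW layout) --------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None) -> "Tensor":
        """Stride-1 'same' cross-correlation. weight: (F, C, kh, kw)."""
        x = self.data
        w = weight.data
        n, c, h, ww = x.shape
        f, _, kh, kw = w.shape
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        # (N, C, H, W, kh, kw) view; reshape to matmul for BLAS speed
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * ww, c * kh * kw)
        col = np.ascontiguousarray(col, dtype=np.float32)
        wmat = w.reshape(f, c * kh * kw)
        y = (col @ wmat.T).reshape(n, h, ww, f).transpose(0, 3, 1, 2)
        if bias is not None:
            y = y + bias.data.reshape(1, f, 1, 1)
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(np.ascontiguousarray(y), parents=parents)

        def bwd(g: np.ndarray) -> None:
            gmat = g.transpose(0, 2, 3, 1).reshape(n * h * ww, f)
            if weight.requires_grad:
                gw = gmat.T @ col
                weight._accumulate(gw.reshape(f, c, kh, kw))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                # dx = "full" correlation of g with the flipped kernel
                gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
                gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
                gcol = gwin.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * ww, f * kh * kw)
                gcol = np.ascontiguousarray(gcol, dtype=np.float32)
                wflip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c, f * kh * kw)
                gx = (gcol @ wflip.T).reshape(n, h, ww, c).transpose(0, 3, 1, 2)
                self._accumulate(np.ascontiguousarray(gx))

        out._backward = bwd
        return out

    def depthwise_conv2d(self, weight: "Tensor") -> "Tensor":
        """Per-channel 'same' cross-correlation. weight: (C, kh, kw), no bias."""
        x = self.data
        w = weight.data
        n, c, h, ww = x.shape
        _, kh, kw = w.shape
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
        y = np.einsum("nchwij,cij->nchw", win, w, optimize=True)
        out = Tensor(np.ascontiguousarray(y, dtype=np.float32), parents=(self, weight))

        def bwd(g: np.ndarray) -> None:
            if weight.requires_grad:
                gw = np.einsum("nchwij,nchw->cij", win, g, optimize=True)
                weight._accumulate(gw.astype(np.float32))
            if self.requires_grad:
                gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
                gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
                wflip = np.ascontiguousarray(w[:, ::-1, ::-1])
                gx = np.einsum("nchwij,cij->nchw", gwin, wflip, optimize=True)
                self._accumulate(gx.astype(np.float32))

        out._backward = bwd
        return out

    def maxpool2x2(self) -> "Tensor":
        n, c, h, w = self.shape
        assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 requires even spatial dims"
        r = self.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        out = Tensor(np.take_along_axis(r, idx[..., None], axis=-1)[..., 0], parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gx = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            self._accumulate(gx)

        out._backward = bwd
        return out

    def avgpool2x2(self) -> "Tensor":
        n, c, h, w = self.shape
        assert h % 2 == 0 and w % 2 == 0, "avgpool2x2 requires even spatial dims"
        y = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        out = Tensor(y, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                gx = (g / 4.0).repeat(2, axis=2).repeat(2, axis=3)
                self._accumulate(gx)

        out._backward = bwd
        return out

    def batchnorm(self, gamma: "Tensor", beta: "Tensor", mean: np.ndarray, invstd: np.ndarray,
                  batch_stats: bool) -> "Tensor":
        """Fused channel-wise normalization: (x - mean) * invstd * gamma + beta.

        When ``batch_stats`` is true, gradients flow through the batch mean
        and variance (training mode); otherwise mean/invstd are constants
        (running statistics, evaluation mode).
        """
        c = self.shape[1]
        mu = mean.reshape(1, c, 1, 1)
        istd = invstd.reshape(1, c, 1, 1)
        xhat = (self.data - mu) * istd
        y = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)
        out = Tensor(y, parents=(self, gamma, beta))

        def bwd(g: np.ndarray) -> None:
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gxhat = g * gamma.data.reshape(1, c, 1, 1)
                if batch_stats:
                    m = gxhat.mean(axis=(0, 2, 3), keepdims=True)
                    mx = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    self._accumulate((istd * (gxhat - m - xhat * mx)).astype(np.float32))
                else:
                    self._accumulate((istd * gxhat).astype(np.float32))

        out._backward = bwd
        return out

    def upsample2x(self) -> "Tensor":
        """Nearest-neighbour 2x spatial upsampling."""
        y = self.data.repeat(2, axis=2).repeat(2, axis=3)
        out = Tensor(y, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            n, c, h, w = g.shape
            gx = g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
            self._accumulate(gx)

        out._backward = bwd
        return out

    def global_avg_pool(self) -> "Tensor":
        """(N, C, H, W) -> (N, C) mean over the spatial axes."""
        n, c, h, w = self.shape
        out = Tensor(self.data.mean(axis=(2, 3)), parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), self.shape).astype(np.float32))

        out._backward = bwd
        return out

    def slice_channels(self, start: int, stop: int) -> "Tensor":
        out = Tensor(self.data[:, start:stop], parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                gx[:, start:stop] = g
                self._accumulate(gx)

        out._backward = bwd
        return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out
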