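"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the slice encoder, the attention
fusion and the risk network: broadcast arithmetic, matmul, relu, exp/log,
reductions, advanced indexing, concatenation, cumulative sums, a numerically
stable log-softmax and a strided 2D convolution (im2col). Gradients are
accumulated in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(-grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-grad * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ grad)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(grad * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def exp(self):
        value = np.exp(self.data)

        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(grad * value)

        return Tensor._make(value, (self,), backward)

    def log(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(grad / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    # -- reductions and shape -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(grad, out):
            if not self.requires_grad:
                return
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def max(self, axis: int, keepdims: bool = False):
        idx = self.data.argmax(axis=axis)
        value = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def backward(grad, out):
            if not self.requires_grad:
                return
            g = grad if keepdims else np.expand_dims(grad, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accumulate(full)

        out_value = value if keepdims else value.squeeze(axis)
        return Tensor._make(out_value, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(grad.reshape(self.data.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or None
        inv = np.argsort(axes) if axes else None

        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(grad.transpose(inv) if inv is not None else grad.T)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def backward(grad, out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, grad)
                self._accumulate(g)

        return Tensor._make(self.data[idx], (self,), backward)

    def cumsum(self, axis: int):
        def backward(grad, out):
            if self.requires_grad:
                flipped = np.flip(grad, axis=axis)
                self._accumulate(np.flip(np.cumsum(flipped, axis=axis), axis=axis))

        return Tensor._make(np.cumsum(self.data, axis=axis), (self,), backward)

    # -- stable softmax -------------------------------------------------------
    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        value = shifted - logsumexp
        softmax = np.exp(value)

        def backward(grad, out):
            if self.requires_grad:
                self._accumulate(grad - softmax * grad.sum(axis=axis, keepdims=True))

        return Tensor._make(value, (self,), backward)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    # -- convolution (NCHW, stride, zero padding) -----------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1, padding: int = 0):
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        oc, _, kh, kw = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        oh = (h + 2 * padding - kh) // stride + 1
        ow = (wd + 2 * padding - kw) // stride + 1
        # im2col: (n, oh, ow, c*kh*kw)
        s0, s1, s2, s3 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, oh, ow, c, kh, kw),
            strides=(s0, s2 * stride, s3 * stride, s1, s2, s3),
        ).reshape(n * oh * ow, c * kh * kw)
        wmat = w.reshape(oc, -1)
        out = (cols @ wmat.T).reshape(n, oh, ow, oc).transpose(0, 3, 1, 2) + bias.data.reshape(
            1, oc, 1, 1
        )

        def backward(grad, out_t):
            gout = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, oc)
            if weight.requires_grad:
                weight._accumulate((gout.T @ cols).reshape(w.shape))
            if bias.requires_grad:
                bias._accumulate(gout.sum(axis=0))
            if self.requires_grad:
                gcols = gout @ wmat  # (n*oh*ow, c*kh*kw)
                gxp = np.zeros_like(xp)
                gcols6 = gcols.reshape(n, oh, ow, c, kh, kw)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += (
                            gcols6[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                        )
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accumulate(gxp)

        return Tensor._make(out, (self, weight, bias), backward)

    # -- backward driver ------------------------------------------------------
    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad, node)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * grad.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(grad[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]

    def backward(grad, out):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(grad, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward)
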