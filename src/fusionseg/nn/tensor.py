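"""A compact tape-based autograd engine for 2-D convolutional networks.

Arrays are numpy ``float32`` throughout. A :class:`Tensor` wraps an array
and records, for every differentiable operation, a closure that pushes the
upstream gradient to its parents; :meth:`Tensor.backward` runs the tape in
reverse topological order. Only the operations the segmentation network
needs are implemented (stride-1 dilated convolution, 2x2 stride-2
transposed convolution and max-pooling, batch-norm, the usual elementwise
algebra, softmax and its cross-entropy), each with a hand-written backward
pass so the whole engine stays a few hundred lines of numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "maximum",
    "conv2d",
    "conv_transpose2x2",
    "max_pool2x2",
    "batch_norm",
    "dropout",
    "softmax",
    "softmax_cross_entropy",
]

_F32 = np.float32


class Tensor:
    """An array node on the autograd tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_F32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this node (default seed: ones)."""
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=_F32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # release the tape as we go: closures hold the saved
                # activations, and interior gradients are fully consumed
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None

    # -- algebra ----------------------------------------------------------

    def __add__(self, other):
        return _elementwise(self, other, np.add, lambda a, b, g: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _elementwise(self, other, np.subtract, lambda a, b, g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _elementwise(
            self, other, np.multiply, lambda a, b, g: (g * b, g * a)
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _elementwise(
            self,
            other,
            np.divide,
            lambda a, b, g: (g / b, -g * a / (b * b)),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return self * -1.0

    def sqrt(self) -> "Tensor":
        out = Tensor(np.sqrt(self.data))
        _attach(out, (self,), lambda g: self._accumulate(g * 0.5 / np.maximum(out.data, 1e-12)))
        return out

    def clamp(self, lo: float, hi: float) -> "Tensor":
        out = Tensor(np.clip(self.data, lo, hi))
        inside = (self.data > lo) & (self.data < hi)
        _attach(out, (self,), lambda g: self._accumulate(g * inside))
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0))
        mask = self.data > 0
        _attach(out, (self,), lambda g: self._accumulate(g * mask))
        return out

    def sigmoid(self) -> "Tensor":
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s)
        _attach(out, (self,), lambda g: self._accumulate(g * s * (1.0 - s)))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        _attach(out, (self,), back)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else _axis_count(self.data.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape))
        _attach(out, (self,), lambda g: self._accumulate(g.reshape(orig)))
        return out

    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        """Contiguous slice along one axis (differentiable)."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = Tensor(self.data[idx])

        def back(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        _attach(out, (self,), back)
        return out

    def broadcast_spatial(self, h: int, w: int) -> "Tensor":
        """Broadcast an (N, C, 1, 1) map to (N, C, h, w)."""
        n, c = self.data.shape[:2]
        out = Tensor(np.broadcast_to(self.data, (n, c, h, w)).copy())
        _attach(
            out,
            (self,),
            lambda g: self._accumulate(g.sum(axis=(2, 3), keepdims=True)),
        )
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _attach(out: Tensor, parents: tuple, back) -> None:
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if any(p.requires_grad or p._parents or p._backward for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = back


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient to the shape it was broadcast from."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.astype(_F32, copy=False)


def _elementwise(a, b, fwd, grads) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(fwd(a.data, b.data))

    def back(g):
        ga, gb = grads(a.data, b.data, g)
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    _attach(out, (a, b), back)
    return out


def _axis_count(shape, axis) -> int:
    if isinstance(axis, int):
        axis = (axis,)
    n = 1
    for ax in axis:
        n *= shape[ax]
    return n


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum; ties route their gradient to the first input."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data >= b.data
    out = Tensor(np.where(take_a, a.data, b.data))

    def back(g):
        a._accumulate(_unbroadcast(g * take_a, a.data.shape))
        b._accumulate(_unbroadcast(g * ~take_a, b.data.shape))

    _attach(out, (a, b), back)
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    _attach(out, tuple(tensors), back)
    return out


# -- structured ops -------------------------------------------------------


def _im2col(xp: np.ndarray, k: int, dilation: int, oh: int, ow: int) -> np.ndarray:
    """Gather padded input into a (N, C*k*k, oh*ow) patch matrix."""
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        hi = i * dilation
        for j in range(k):
            wj = j * dilation
            cols[:, :, i, j] = xp[:, :, hi : hi + oh, wj : wj + ow]
    return cols.reshape(n, c * k * k, oh * ow)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    padding: int = 1,
    dilation: int = 1,
) -> Tensor:
    """Stride-1 2-D convolution; padding chosen by callers to keep size."""
    n, c, h, w = x.data.shape
    o, ci, k, _ = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ci}")
    oh = h + 2 * padding - dilation * (k - 1)
    ow = w + 2 * padding - dilation * (k - 1)
    if oh <= 0 or ow <= 0:
        raise ValueError("conv2d output would be empty")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, k, dilation, oh, ow)
    wmat = weight.data.reshape(o, c * k * k)
    y = np.matmul(wmat, cols).reshape(n, o, oh, ow)
    del cols  # the backward pass recomputes patch products from xp
    if bias is not None:
        y = y + bias.data.reshape(1, o, 1, 1)
    out = Tensor(y)

    def back(g):
        gmat = np.ascontiguousarray(g.reshape(n, o, oh * ow))
        need_gx = x.requires_grad or x._parents or x._backward
        gw = np.empty((o, c, k, k), dtype=xp.dtype)
        gxp = np.zeros_like(xp) if need_gx else None
        # per-offset batched sgemm keeps transients at input size instead of
        # materializing the 9x patch matrix again
        for i in range(k):
            hi = i * dilation
            for j in range(k):
                wj = j * dilation
                xs = xp[:, :, hi : hi + oh, wj : wj + ow].reshape(n, c, oh * ow)
                gw[:, :, i, j] = np.matmul(gmat, xs.transpose(0, 2, 1)).sum(axis=0)
                if need_gx:
                    wij = weight.data[:, :, i, j]  # (o, c)
                    gxp[:, :, hi : hi + oh, wj : wj + ow] += np.matmul(
                        wij.T, gmat
                    ).reshape(n, c, oh, ow)
        weight._accumulate(gw)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if need_gx:
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(np.ascontiguousarray(gxp))

    parents = (x, weight) if bias is None else (x, weight, bias)
    _attach(out, parents, back)
    return out


def conv_transpose2x2(x: Tensor, weight: Tensor) -> Tensor:
    """2x2, stride-2 transposed convolution (doubles spatial size).

    ``weight`` has shape (in_ch, out_ch, 2, 2).
    """
    n, c, h, w = x.data.shape
    ci, o, _, _ = weight.data.shape
    if ci != c:
        raise ValueError(f"conv_transpose channel mismatch: {c} vs {ci}")
    y = np.empty((n, o, 2 * h, 2 * w), dtype=_F32)
    xmat = x.data.reshape(n, c, h * w)
    for i in range(2):
        for j in range(2):
            piece = np.matmul(weight.data[:, :, i, j].T, xmat)
            y[:, :, i::2, j::2] = piece.reshape(n, o, h, w)
    out = Tensor(y)

    def back(g):
        gw = np.empty_like(weight.data)
        gx = np.zeros_like(x.data)
        for i in range(2):
            for j in range(2):
                gij = np.ascontiguousarray(g[:, :, i::2, j::2].reshape(n, o, h * w))
                gw[:, :, i, j] = np.matmul(xmat, gij.transpose(0, 2, 1)).sum(axis=0)
                gx += np.matmul(weight.data[:, :, i, j], gij).reshape(n, c, h, w)
        weight._accumulate(gw)
        x._accumulate(gx)

    _attach(out, (x, weight), back)
    return out


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling; halves both spatial sides."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 needs even spatial sides, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = np.ascontiguousarray(blocks).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0])

    def back(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        x._accumulate(
            gflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    _attach(out, (x,), back)
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization on (N, C, H, W)."""
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        m = n * h * w
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = Tensor(gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None])

    def back(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        if not (x.requires_grad or x._parents or x._backward):
            return
        gi = g * gamma.data[None, :, None, None]
        if training:
            m = n * h * w
            gx = (
                gi
                - gi.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (gi * xhat).mean(axis=(0, 2, 3), keepdims=True)
            ) * inv[None, :, None, None]
            x._accumulate(gx.astype(_F32, copy=False))
        else:
            x._accumulate(gi * inv[None, :, None, None])

    _attach(out, (x, gamma, beta), back)
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate).astype(_F32) / (1.0 - rate)
    out = Tensor(x.data * keep)
    _attach(out, (x,), lambda g: x._accumulate(g * keep))
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p)

    def back(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        x._accumulate(p * (g - dot))

    _attach(out, (x,), back)
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel NLL of the integer ``labels`` under softmax(logits).

    ``logits``: (N, K, H, W); ``labels``: (N, H, W) ints in [0, K).
    """
    n, k, h, w = logits.data.shape
    labels = np.asarray(labels)
    if labels.shape != (n, h, w):
        raise ValueError(f"labels shape {labels.shape} != {(n, h, w)}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    picked = np.take_along_axis(p, labels[:, None], axis=1)[:, 0]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    out = Tensor(loss)

    def back(g):
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
        logits._accumulate((p - onehot) * (float(g) / (n * h * w)))

    _attach(out, (logits,), back)
    return out
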