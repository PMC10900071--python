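"""Minimal reverse-mode automatic differentiation on numpy arrays.

A ``Tensor`` wraps an ndarray and records the operations applied to it on a
tape; ``Tensor.backward()`` walks the tape in reverse topological order and
accumulates gradients. Only the operations needed by the models in this
package are provided (elementwise arithmetic, matmul, reductions, indexing,
embedding lookup, 3D convolution, nearest-neighbour upsampling, concat).

Shapes broadcast like numpy; gradients are summed back down to the operand
shape. All floating point work is float32 unless the caller passes float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad"]


class _NoGrad:
    """Context manager that disables tape recording (inference mode)."""

    _enabled = True  # True = gradients are recorded

    def __enter__(self):
        self._prev = _NoGrad._enabled
        _NoGrad._enabled = False
        return self

    def __exit__(self, *exc):
        _NoGrad._enabled = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    a = np.asarray(x)
    if a.dtype.kind in "iub":
        a = a.astype(np.float32)
    return a


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        a = np.asarray(data)
        if a.dtype.kind in "iub":
            a = a.astype(np.float32)
        self.data: np.ndarray = a
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _NoGrad._enabled
        self._backward = None
        self._prev: tuple = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if out.requires_grad:
            out._prev = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64 if self.data.dtype == np.float64 else np.float32)
        self.grad += g.astype(self.grad.dtype, copy=False)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        ob = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + ob.data
        req = self.requires_grad or ob.requires_grad

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            ob._accumulate(_unbroadcast(g, ob.data.shape))

        return Tensor._make(data, (self, ob), backward, req)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        ob = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data - ob.data
        req = self.requires_grad or ob.requires_grad

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            ob._accumulate(_unbroadcast(-g, ob.data.shape))

        return Tensor._make(data, (self, ob), backward, req)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        ob = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * ob.data
        req = self.requires_grad or ob.requires_grad

        def backward(g):
            self._accumulate(_unbroadcast(g * ob.data, self.data.shape))
            ob._accumulate(_unbroadcast(g * self.data, ob.data.shape))

        return Tensor._make(data, (self, ob), backward, req)

    __rmul__ = __mul__

    def __truediv__(self, other):
        ob = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data / ob.data
        req = self.requires_grad or ob.requires_grad

        def backward(g):
            self._accumulate(_unbroadcast(g / ob.data, self.data.shape))
            ob._accumulate(_unbroadcast(-g * self.data / (ob.data ** 2), ob.data.shape))

        return Tensor._make(data, (self, ob), backward, req)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        data = self.data ** p

        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * data)

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def log(self):
        data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - data ** 2))

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def relu(self):
        mask = self.data > 0
        data = np.where(mask, self.data, 0.0)

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def leaky_relu(self, alpha: float = 0.01):
        mask = self.data > 0
        data = np.where(mask, self.data, alpha * self.data)

        def backward(g):
            self._accumulate(g * np.where(mask, 1.0, alpha))

        return Tensor._make(data, (self,), backward, self.requires_grad)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        data = self.data.transpose(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def swapaxes(self, a: int, b: int):
        data = self.data.swapaxes(a, b)

        def backward(g):
            self._accumulate(g.swapaxes(a, b))

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(data, (self,), backward, self.requires_grad)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor"):
        ob = other if isinstance(other, Tensor) else Tensor(other)
        data = np.matmul(self.data, ob.data)
        req = self.requires_grad or ob.requires_grad

        def backward(g):
            ga = np.matmul(g, ob.data.swapaxes(-1, -2))
            gb = np.matmul(self.data.swapaxes(-1, -2), g)
            self._accumulate(_unbroadcast(ga, self.data.shape))
            ob._accumulate(_unbroadcast(gb, ob.data.shape))

        return Tensor._make(data, (self, ob), backward, req)

    __matmul__ = matmul

    # -- fused normalisers --------------------------------------------------
    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        data = shifted - lse

        def backward(g):
            sm = np.exp(data)
            self._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._make(data, (self,), backward, self.requires_grad)

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * data).sum(axis=axis, keepdims=True)
            self._accumulate(data * (g - dot))

        return Tensor._make(data, (self,), backward, self.requires_grad)


# -- non-method ops ---------------------------------------------------------

def concat(tensors: list, axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor._make(data, tuple(tensors), backward, req)


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add gradient."""
    idx = np.asarray(idx)
    data = weight.data[idx]

    def backward(g):
        if weight.requires_grad:
            if weight.grad is None:
                weight.grad = np.zeros_like(weight.data)
            np.add.at(weight.grad, idx, g.astype(weight.grad.dtype, copy=False))

    return Tensor._make(data, (weight,), backward, weight.requires_grad)


def gather_last(t: Tensor, idx: np.ndarray) -> Tensor:
    """Pick ``t[..., idx]`` elementwise along the last axis (idx shape = t.shape[:-1])."""
    idx = np.asarray(idx)
    data = np.take_along_axis(t.data, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        full = np.zeros_like(t.data)
        np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
        t._accumulate(full)

    return Tensor._make(data, (t,), backward, t.requires_grad)


def straight_through(z_e: Tensor, z_q: np.ndarray) -> Tensor:
    """Return quantised values, pass gradients to the continuous latents unchanged."""

    def backward(g):
        z_e._accumulate(g)

    return Tensor._make(np.asarray(z_q, dtype=z_e.data.dtype), (z_e,), backward, z_e.requires_grad)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3D convolution, NCDHW layout; w is (out_c, in_c, kd, kh, kw).

    im2col + one GEMM on the forward pass; the input gradient is scattered
    back with one strided add per kernel offset.
    """
    B, C, D, H, W = x.data.shape
    O, Ci, kd, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
    s, p = stride, padding
    if kd == kh == kw == 1 and s == 1 and p == 0:
        return _conv3d_1x1(x, w, b)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    Do = (D + 2 * p - kd) // s + 1
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    vox = Do * Ho * Wo
    cols = np.empty((B, C, kd, kh, kw, vox), dtype=xp.dtype)
    for a in range(kd):
        for bb in range(kh):
            for c in range(kw):
                xs = xp[:, :, a:a + s * Do:s, bb:bb + s * Ho:s, c:c + s * Wo:s]
                cols[:, :, a, bb, c] = xs.reshape(B, C, vox)
    cols = cols.reshape(B, C * kd * kh * kw, vox)
    w2 = w.data.reshape(O, -1)
    out = np.matmul(w2, cols).reshape(B, O, Do, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, O, 1, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)

    def backward(g):
        g2 = g.reshape(B, O, vox)
        if w.requires_grad:
            w._accumulate(np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
                          .reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.matmul(w2.T, g2).reshape(B, C, kd, kh, kw, Do, Ho, Wo)
            gxp = np.zeros_like(xp)
            for a in range(kd):
                for bb in range(kh):
                    for c in range(kw):
                        gxp[:, :, a:a + s * Do:s, bb:bb + s * Ho:s, c:c + s * Wo:s] += \
                            gcols[:, :, a, bb, c]
            x._accumulate(gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward, req)


def _conv3d_1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution: a single channel-mixing GEMM, no im2col."""
    B, C, D, H, W = x.data.shape
    O = w.data.shape[0]
    w2 = w.data.reshape(O, C)
    out = np.matmul(w2, x.data.reshape(B, C, -1)).reshape(B, O, D, H, W)
    if b is not None:
        out += b.data.reshape(1, O, 1, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)

    def backward(g):
        g2 = g.reshape(B, O, -1)
        if w.requires_grad:
            w._accumulate(np.matmul(g2, x.data.reshape(B, C, -1).transpose(0, 2, 1))
                          .sum(axis=0).reshape(w.data.shape))
        if x.requires_grad:
            x._accumulate(np.matmul(w2.T, g2).reshape(x.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward, req)


def upsample_nearest3d(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor along each spatial axis."""
    f = int(factor)
    data = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)

    def backward(g):
        B, C, D, H, W = x.data.shape
        gs = g.reshape(B, C, D, f, H, f, W, f).sum(axis=(3, 5, 7))
        x._accumulate(gs)

    return Tensor._make(data, (x,), backward, x.requires_grad)


def spectral_l2(recon: Tensor, target: np.ndarray, axes: tuple | None = None) -> Tensor:
    """L2 loss between full complex DFTs of recon and target.

    loss = mean_k |F(recon - target)_k|^2 / N where the DFT runs over ``axes``
    (default: all axes; pass the spatial axes for batched inputs) and N is the
    number of transformed voxels. By Parseval this equals the spatial MSE; it
    is computed in the Fourier domain regardless, and the exact gradient is
    2 * (recon - target) / size.
    """
    diff = recon.data - np.asarray(target, dtype=recon.data.dtype)
    n = diff.size if axes is None else int(np.prod([diff.shape[a] for a in axes]))
    F = np.fft.fftn(diff, axes=axes)
    val = float(np.mean(np.abs(F) ** 2) / n)

    def backward(g):
        recon._accumulate(g * 2.0 * diff / diff.size)

    return Tensor._make(np.asarray(val, dtype=recon.data.dtype), (recon,),
                        backward, recon.requires_grad)
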