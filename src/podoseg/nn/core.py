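"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the segmentation U-Net and the cycleGAN
need: elementwise arithmetic and activations, reductions, 2-D convolution
(tap-wise BLAS matmuls), zero-dilation (for transposed convolution),
padding/cropping, 2x2 max pooling, channel concatenation and moment
normalization. Gradients are accumulated on a topologically sorted tape.

All tensors are float32 in NHWC layout (batch, height, width, channels):
channels-last keeps every convolution tap a contiguous matmul operand.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "zero_dilate",
    "pad2d",
    "maxpool2x2",
    "normalize",
    "channel_affine",
    "weighted_bce",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen, stack = [], set(), [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate grads? keep: params need them; intermediates are
            # garbage-collected with the graph.

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # take ownership of freshly allocated float32 arrays; copy views
            # and dtype mismatches (ops that hand one buffer to two parents
            # copy for the second parent themselves)
            if grad.dtype == np.float32 and grad.base is None and \
                    grad.flags.owndata:
                self.grad = grad
            else:
                self.grad = grad.astype(np.float32)
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                go = _unbroadcast(g, other.data.shape)
                other._accum(go.copy() if go is g and self.requires_grad
                             else go)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bwd
        return out

    # -- activations ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bwd
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope).astype(np.float32))

        out._backward = bwd
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bwd
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * sign)

        out._backward = bwd
        return out

    def square(self):
        out = Tensor(self.data * self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * 2.0 * self.data)

        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        """Clip values; gradient is 1 inside [lo, hi] and 0 outside."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * inside)

        out._backward = bwd
        return out

    # -- reductions ----------------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape).astype(np.float32))

        out._backward = bwd
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.data.shape).astype(np.float32))

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        orig = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------------
def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def pad2d(x: Tensor, pad) -> Tensor:
    """Zero-pad spatial dims of an NHWC tensor. pad = (top, bottom, left, right)."""
    t, b, l, r = pad
    out_data = np.pad(x.data, ((0, 0), (t, b), (l, r), (0, 0)))
    out = Tensor(out_data, parents=(x,))
    H, W = x.data.shape[1:3]

    def bwd(g):
        if x.requires_grad:
            x._accum(g[:, t:t + H, l:l + W, :])

    out._backward = bwd
    return out


def zero_dilate(x: Tensor, stride: int, extra: int = 0) -> Tensor:
    """Insert stride-1 zeros between spatial elements; append `extra` zero
    rows/cols at bottom/right (transposed-convolution output padding)."""
    if stride == 1 and extra == 0:
        return x
    N, H, W, C = x.data.shape
    Hd = (H - 1) * stride + 1 + extra
    Wd = (W - 1) * stride + 1 + extra
    out_data = np.zeros((N, Hd, Wd, C), dtype=np.float32)
    out_data[:, ::stride, ::stride, :][:, :H, :W, :] = x.data
    out = Tensor(out_data, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g[:, ::stride, ::stride, :][:, :H, :W, :])

    out._backward = bwd
    return out


def _same_pad(size: int, k: int, s: int) -> tuple:
    """TensorFlow-style SAME padding amounts (before, after) for one dim."""
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding="same") -> Tensor:
    """2-D cross-correlation. x: (N,H,W,Cin); w: (kh,kw,Cin,Cout).

    padding: 'same', 'valid', int (symmetric) or 4-tuple (top,bottom,left,right).
    Computed as one matmul per kernel tap on contiguous channel slices.
    """
    N, H, W, Cin = x.data.shape
    kh, kw, Cin2, Cout = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin}, weight expects {Cin2}")
    if padding == "same":
        pt, pb = _same_pad(H, kh, stride)
        pl, pr = _same_pad(W, kw, stride)
    elif padding == "valid":
        pt = pb = pl = pr = 0
    elif isinstance(padding, int):
        pt = pb = pl = pr = padding
    else:
        pt, pb, pl, pr = padding

    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0))) \
        if (pt or pb or pl or pr) else x.data
    Hp, Wp = xp.shape[1:3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    s = stride

    def tap(arr, i, j):
        return arr[:, i:i + (Ho - 1) * s + 1:s, j:j + (Wo - 1) * s + 1:s, :]

    if kh == kw == 1 and s == 1:
        out_data = (xp.reshape(-1, Cin) @ w.data[0, 0]).reshape(N, Ho, Wo, Cout)
    elif s == 1:
        # one large GEMM per tap on row-contiguous slabs (a few redundant
        # columns per row are computed and discarded by the shifted add)
        out_data = np.zeros((N, Ho, Wo, Cout), dtype=np.float32)
        buf = np.empty((N * Ho * Wp, Cout), dtype=np.float32)
        for i in range(kh):
            rows = xp[:, i:i + Ho, :, :].reshape(-1, Cin)
            for j in range(kw):
                np.matmul(rows, w.data[i, j], out=buf)
                out_data += buf.reshape(N, Ho, Wp, Cout)[:, :, j:j + Wo, :]
    else:
        out_data = np.zeros((N, Ho, Wo, Cout), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                out_data += tap(xp, i, j) @ w.data[i, j]
    if b is not None:
        out_data += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def bwd(g):
        g2 = g.reshape(-1, Cout)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if w.requires_grad:
            if kh == kw == 1 and s == 1:
                gw = (xp.reshape(-1, Cin).T @ g2)[None, None]
            else:
                gw = np.empty_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        # batched GEMM over (N, Ho): (Cin, Wo) @ (Wo, Cout)
                        gw[i, j] = (np.swapaxes(tap(xp, i, j), 2, 3)
                                    @ g).sum(axis=(0, 1))
            w._accum(gw)
        if x.requires_grad:
            if kh == kw == 1 and s == 1:
                dxp = (g2 @ w.data[0, 0].T).reshape(xp.shape)
            else:
                dxp = np.zeros_like(xp)
                gt = np.empty((N * Ho * Wo, Cin), dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        np.matmul(g2, w.data[i, j].T, out=gt)
                        tap(dxp, i, j)[...] += gt.reshape(N, Ho, Wo, Cin)
            x._accum(dxp[:, pt:pt + H, pl:pl + W, :]
                     if (pt or pb or pl or pr) else dxp)

    out._backward = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    N, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 needs even spatial dims")
    Ho, Wo = H // 2, W // 2
    xr = x.data.reshape(N, Ho, 2, Wo, 2, C).transpose(0, 1, 3, 5, 2, 4).reshape(
        N, Ho, Wo, C, 4)
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros((N, Ho, Wo, C, 4), dtype=np.float32)
            np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
            gx = gx.reshape(N, Ho, Wo, C, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
                N, H, W, C)
            x._accum(gx)

    out._backward = bwd
    return out


def normalize(x: Tensor, axes: tuple, eps: float = 1e-5,
              moments=None) -> Tensor:
    """(x - mean) / sqrt(var + eps) with moments over `axes`; precomputed
    (mean, var) keepdims arrays can be passed to avoid a second pass."""
    if moments is None:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
    else:
        mu, var = moments
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat, parents=(x,))
    m = np.prod([x.data.shape[a] for a in axes])

    def bwd(g):
        if x.requires_grad:
            gm = g.mean(axis=axes, keepdims=True)
            gxm = (g * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv * (g - gm - xhat * gxm))

    out._backward = bwd
    return out


def channel_affine(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """y = x * gamma + beta with per-channel (last axis) parameters,
    fused so the backward pass does one product and two reductions."""
    out = Tensor(x.data * gamma.data + beta.data, parents=(x, gamma, beta))
    red = tuple(range(x.data.ndim - 1))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * x.data).sum(axis=red))
        if beta.requires_grad:
            beta._accum(g.sum(axis=red))
        if x.requires_grad:
            x._accum(g * gamma.data)

    out._backward = bwd
    return out


def weighted_bce(p: Tensor, y: np.ndarray, weights=None,
                 epsilon: float = 1e-7) -> Tensor:
    """mean over pixels of -w [y log p~ + (1-y) log(1-p~)] with the
    prediction clipped to [eps, 1-eps] (the clip also gates the gradient)."""
    y = np.asarray(y, dtype=np.float32)
    if y.shape != p.data.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {p.data.shape}")
    pc = np.clip(p.data, epsilon, 1.0 - epsilon)
    term = y * np.log(pc) + (1.0 - y) * np.log1p(-pc)
    if weights is not None:
        term = term * weights
    out = Tensor(-term.mean(), parents=(p,))
    n = term.size

    def bwd(g):
        if p.requires_grad:
            inside = (p.data >= epsilon) & (p.data <= 1.0 - epsilon)
            dp = (pc - y) / (pc * (1.0 - pc) * n)
            if weights is not None:
                dp = dp * weights
            p._accum((float(g) * dp * inside).astype(np.float32))

    out._backward = bwd
    return out
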