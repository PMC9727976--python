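"""Minimal reverse-mode autodiff engine and neural-network layers on NumPy.

Implements exactly the operations the segmentation network needs: 2-D
convolution (stride / padding / dilation) via im2col, transposed convolution,
batch normalisation, leaky ReLU, max pooling, bilinear resizing, channel-wise
max/mean reductions, concatenation and a fused softmax cross-entropy, plus SGD
with momentum and weight decay.  Gradients are verified against central
differences in the test suite.

Tensors wrap ``numpy`` arrays; the default dtype is float32 and every op
preserves the dtype of its inputs, so gradient checks can run in float64.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(DEFAULT_DTYPE)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        """Reverse-mode sweep from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # Small conveniences used by the layers -------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def detach(self):
        return Tensor(self.data.copy())


def _node(data, parents, backward):
    out = Tensor(data)
    track = any(p.requires_grad or p._parents or p._backward for p in parents)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), backward)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * np.where(mask, 1.0, slope).astype(g.dtype))

    return _node(np.where(mask, x.data, slope * x.data), (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def channel_max(x: Tensor) -> Tensor:
    """Max over the channel axis of an (N, C, H, W) tensor -> (N, 1, H, W)."""
    idx = np.argmax(x.data, axis=1)[:, None]

    def backward(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, g, axis=1)
        x._accumulate(gx)

    return _node(np.take_along_axis(x.data, idx, axis=1), (x,), backward)


def channel_mean(x: Tensor) -> Tensor:
    c = x.data.shape[1]

    def backward(g):
        x._accumulate(np.broadcast_to(g / c, x.data.shape).copy())

    return _node(x.data.mean(axis=1, keepdims=True), (x,), backward)


# ---------------------------------------------------------------------------
# convolution via im2col / col2im
# ---------------------------------------------------------------------------

def conv_out_size(w_in: int, p: int, d: int, k: int, s: int) -> int:
    """Spatial output size of a (dilated) convolution, floor convention."""
    out = (w_in + 2 * p - d * (k - 1) - 1) // s + 1
    if out <= 0:
        raise ValueError(
            f"non-positive conv output size for w_in={w_in}, p={p}, d={d}, "
            f"k={k}, s={s}")
    return out


def _im2col(x, k, stride, pad, dil):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = conv_out_size(h, pad, dil, k, stride)
    ow = conv_out_size(w, pad, dil, k, stride)
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :,
                                 i * dil:i * dil + stride * oh:stride,
                                 j * dil:j * dil + stride * ow:stride]
    return cols.reshape(n, c * k * k, oh * ow), oh, ow


def _col2im(cols, x_shape, k, stride, pad, dil, oh, ow):
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[:, :,
               i * dil:i * dil + stride * oh:stride,
               j * dil:j * dil + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        xp = xp[:, :, pad:pad + h, pad:pad + w]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           pad: int = 0, dil: int = 1) -> Tensor:
    """x: (N,C,H,W); w: (O,C,k,k); b: (O,) or None."""
    o, c, k, _ = w.data.shape
    cols, oh, ow = _im2col(x.data, k, stride, pad, dil)
    w2 = w.data.reshape(o, -1)
    out = np.matmul(w2[None], cols)
    if b is not None:
        out += b.data[None, :, None]
    n = x.data.shape[0]

    def backward(g):
        gr = g.reshape(n, o, -1)
        w._accumulate(
            np.matmul(gr, cols.transpose(0, 2, 1)).sum(axis=0)
            .reshape(w.data.shape))
        if b is not None:
            b._accumulate(gr.sum(axis=(0, 2)))
        dcols = np.matmul(w2.T[None], gr)
        x._accumulate(_col2im(dcols, x.data.shape, k, stride, pad, dil, oh, ow))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out.reshape(n, o, oh, ow), parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2,
                     pad: int = 1, out_pad: int = 1) -> Tensor:
    """Transposed convolution; w: (C_in, C_out, k, k).  Default geometry
    (k=3, s=2, p=1, op=1) exactly doubles the spatial size."""
    ci, co, k, _ = w.data.shape
    n, _, h, win = x.data.shape
    oh = (h - 1) * stride - 2 * pad + k + out_pad
    ow = (win - 1) * stride - 2 * pad + k + out_pad
    w2 = w.data.reshape(ci, -1)
    xr = x.data.reshape(n, ci, h * win)
    cols = np.matmul(w2.T[None], xr)
    out = _col2im(cols, (n, co, oh, ow), k, stride, pad, 1, h, win)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        dcols, _, _ = _im2col(g, k, stride, pad, 1)
        dcols = dcols[:, :, :h * win]
        x._accumulate(np.matmul(w2[None], dcols).reshape(x.data.shape))
        w._accumulate(
            np.matmul(xr, dcols.transpose(0, 2, 1)).sum(axis=0)
            .reshape(w.data.shape))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def max_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping max pooling (stride == kernel); trailing rows/columns
    that do not fill a window are dropped (floor convention)."""
    n, c, h, w = x.data.shape
    oh, ow = h // k, w // k
    if oh < 1 or ow < 1:
        raise ValueError(f"pool kernel {k} exceeds spatial size {h}x{w}")
    xc = x.data[:, :, :oh * k, :ow * k]
    v = xc.reshape(n, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5)
    v = v.reshape(n, c, oh, ow, k * k)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gv = np.zeros((n, c, oh, ow, k * k), dtype=g.dtype)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, :oh * k, :ow * k] = (
            gv.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
              .reshape(n, c, oh * k, ow * k))
        x._accumulate(gx)

    return _node(out, (x,), backward)


def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centres)."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = src - i0
    for r in range(n_out):
        a[r, i0[r]] += 1 - t[r]
        a[r, i1[r]] += t[r]
    return a


def bilinear_resize(x: Tensor, out_hw) -> Tensor:
    oh, ow = out_hw
    n, c, h, w = x.data.shape
    ah = _resize_matrix(h, oh, x.data.dtype)
    aw = _resize_matrix(w, ow, x.data.dtype)
    out = ah @ x.data @ aw.T

    def backward(g):
        x._accumulate(ah.T @ g @ aw)

    return _node(out, (x,), backward)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, C, H, W) logits against integer labels."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    t = target[:, None]
    npix = target.size
    picked = np.take_along_axis(p, t, axis=1)
    loss = -np.log(np.maximum(picked, 1e-30)).sum() / npix

    def backward(g):
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, t, 1.0, axis=1)
        logits._accumulate(g * (p - onehot) / npix)

    return _node(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
               running_var, momentum: float = 0.1, eps: float = 1e-5,
               training: bool = True) -> Tensor:
    """Batch normalisation over (N, H, W) per channel; updates running stats
    in place while training."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gi = g * gamma.data[None, :, None, None]
        if training:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            s1 = gi.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = inv[None, :, None, None] * (gi - s1 / m - xhat * s2 / m)
        else:
            gx = gi * inv[None, :, None, None]
        x._accumulate(gx.astype(x.data.dtype))

    return _node(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery and train/eval mode switching."""

    training: bool = True

    def parameters(self):
        params, seen = [], set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def _submodules(self):
        subs = []

        def collect(obj):
            if isinstance(obj, Module):
                subs.append(obj)
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        for v in vars(self).values():
            collect(v)
        return subs

    def train(self):
        self.training = True
        for m in self._submodules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self._submodules():
            m.training = False
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def state_arrays(self):
        """Flat list of all learnable and running-stat arrays, in a stable
        traversal order, for checkpointing."""
        arrays = []
        for p in self.parameters():
            arrays.append(p.data)
        for m in self._submodules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays


def _he_init(rng, shape, fan_in, dtype=None):
    """Fan-in scaled uniform init, U(-1/sqrt(fan_in), 1/sqrt(fan_in)).

    Markedly better conditioned for SGD at small learning rates than the
    hotter He-normal scale on this architecture (seed-robust convergence)."""
    dtype = dtype or DEFAULT_DTYPE
    bound = np.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, pad=0, dil=1, bias=True):
        self.stride, self.pad, self.dil = stride, pad, dil
        self.weight = Tensor(_he_init(rng, (cout, cin, k, k), cin * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, DEFAULT_DTYPE),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad,
                      self.dil)


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, k, rng, stride=2, pad=1, out_pad=1,
                 bias=True):
        self.stride, self.pad, self.out_pad = stride, pad, out_pad
        self.weight = Tensor(_he_init(rng, (cin, cout, k, k), cin * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, DEFAULT_DTYPE),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride,
                                self.pad, self.out_pad)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(c, DEFAULT_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(c, DEFAULT_DTYPE), requires_grad=True)
        self.running_mean = np.zeros(c, DEFAULT_DTYPE)
        self.running_var = np.ones(c, DEFAULT_DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.momentum, self.eps,
                          self.training)


class LeakyReLU(Module):
    def __init__(self, slope=0.01):
        self.slope = slope

    def forward(self, x):
        return leaky_relu(x, self.slope)


class MaxPool2d(Module):
    def __init__(self, k):
        self.k = k

    def forward(self, x):
        return max_pool2d(x, self.k)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """Stochastic gradient descent with classical momentum and (decoupled from
    the loss) L2 weight decay: v <- mu v + g + wd w;  w <- w - lr v."""

    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
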