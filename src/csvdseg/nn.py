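"""Minimal CPU deep-learning backend: reverse-mode autodiff over numpy arrays.

Provides exactly the primitives the segmentation network needs — 2-D (grouped /
depthwise) convolution, non-overlapping transposed convolution, batch
normalisation, sigmoid/Swish activations, reductions, concatenation — plus an
Adam optimiser with L2 weight decay.  Gradients of every primitive are covered
by numerical-gradient-check tests.

Arrays follow the NCHW layout throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as _expit

__all__ = [
    "Tensor", "Parameter", "Module", "Conv2d", "ConvTranspose2d",
    "BatchNorm2d", "Adam", "sigmoid", "swish", "concat", "set_default_dtype",
]

#: dtype for new tensors; float64 for exact gradient checks, float32 is
#: adequate for training and roughly halves memory traffic
DTYPE = np.float64


def set_default_dtype(dtype):
    global DTYPE
    DTYPE = np.dtype(dtype).type


# ---------------------------------------------------------------------------
# Tensor and autodiff tape
# ---------------------------------------------------------------------------

def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- construction of derived nodes -------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            # copy only when g is a view or dtype differs; fresh results are owned
            if g.base is not None or g.dtype != self.data.dtype:
                g = g.astype(self.data.dtype, copy=True)
            self.grad = g
        else:
            self.grad += g

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data ** 2)

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- elementwise functions ---------------------------------------------
    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / reshaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(np.reshape(g, old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # -- backward pass ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self):
        return Tensor(self.data.copy())


def sigmoid(x: Tensor) -> Tensor:
    s = _expit(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return Tensor._make(s, (x,), backward)


def swish(x: Tensor) -> Tensor:
    """Swish activation x * sigmoid(x); Swish(0) = 0.  Fused primitive."""
    d = x.data
    s = _expit(d)

    def backward(g):
        if x.requires_grad:
            x._accum(g * (s * (1.0 + d * (1.0 - s))))

    return Tensor._make(d * s, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# Convolution primitives
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW; w is (out, in/groups, kh, kw)."""
    xd, wd = x.data, w.data
    n, c, h, wdt = xd.shape
    o, cg, kh, kw = wd.shape
    if c % groups or o % groups or cg != c // groups:
        raise ValueError("channel/group mismatch")
    og = o // groups
    s, p = stride, padding

    # fast path: 1x1 convolution is a channel matmul, no column matrix needed
    if kh == 1 and kw == 1 and p == 0 and groups == 1:
        xs = xd[:, :, ::s, ::s] if s > 1 else xd
        w2 = wd[:, :, 0, 0]                               # (o, c)
        out = np.tensordot(xs, w2, axes=([1], [1])).transpose(0, 3, 1, 2)
        if b is not None:
            out += b.data[None, :, None, None]

        def backward1(gy):
            if b is not None and b.requires_grad:
                b._accum(gy.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.tensordot(gy, xs, axes=([0, 2, 3], [0, 2, 3]))
                w._accum(gw[:, :, None, None])
            if x.requires_grad:
                gxs = np.tensordot(gy, w2, axes=([1], [0])).transpose(0, 3, 1, 2)
                if s > 1:
                    gx = np.zeros_like(xd)
                    gx[:, :, ::s, ::s] = gxs
                else:
                    gx = gxs
                x._accum(gx)

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._make(out, parents, backward1)

    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    ho = (xp.shape[2] - kh) // s + 1
    wo = (xp.shape[3] - kw) // s + 1
    # cols: (n, c, ho, wo, kh, kw)
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]

    depthwise = (groups == c and cg == 1 and og == 1)
    cr = None
    if depthwise:
        out = np.einsum("nchwij,cij->nchw", cols, wd[:, 0], optimize=True)
    elif groups == 1:
        cr = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * kh * kw)
        out = (cr @ wd.reshape(o, -1).T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    else:
        out = np.empty((n, o, ho, wo))
        for g_ in range(groups):
            cs = cols[:, g_ * cg:(g_ + 1) * cg]
            out[:, g_ * og:(g_ + 1) * og] = np.einsum(
                "nchwij,ocij->nohw", cs, wd[g_ * og:(g_ + 1) * og], optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(gy):
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            if depthwise:
                gw = np.einsum("nchwij,nchw->cij", cols, gy, optimize=True)[:, None]
            elif groups == 1:
                gyr = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
                gw = (gyr.T @ cr).reshape(wd.shape)
            else:
                gw = np.empty_like(wd)
                for g_ in range(groups):
                    gw[g_ * og:(g_ + 1) * og] = np.einsum(
                        "nchwij,nohw->ocij", cols[:, g_ * cg:(g_ + 1) * cg],
                        gy[:, g_ * og:(g_ + 1) * og], optimize=True)
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    tgt = gxp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                    if depthwise:
                        tgt += gy * wd[:, 0, i, j][None, :, None, None]
                    elif groups == 1:
                        tgt += np.einsum("nohw,oc->nchw", gy, wd[:, :, i, j],
                                         optimize=True)
                    else:
                        for g_ in range(groups):
                            tgt[:, g_ * cg:(g_ + 1) * cg] += np.einsum(
                                "nohw,oc->nchw", gy[:, g_ * og:(g_ + 1) * og],
                                wd[g_ * og:(g_ + 1) * og, :, i, j], optimize=True)
            gx = gxp[:, :, p:p + h, p:p + wdt] if p else gxp
            x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution with kernel_size == stride (exact upsampling).

    w is (in, out, s, s).  Restricting kernel to the stride keeps output
    windows non-overlapping, which is all the decoders need.
    """
    xd, wd = x.data, w.data
    n, c, h, wdt = xd.shape
    ci, o, kh, kw = wd.shape
    if ci != c or kh != stride or kw != stride:
        raise ValueError("conv_transpose2d requires kernel_size == stride")
    s = stride
    out = np.empty((n, o, h * s, wdt * s))
    for i in range(s):
        for j in range(s):
            out[:, :, i::s, j::s] = np.einsum("nchw,co->nohw", xd, wd[:, :, i, j],
                                              optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(gy):
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.empty_like(wd)
            for i in range(s):
                for j in range(s):
                    gw[:, :, i, j] = np.einsum("nchw,nohw->co", xd, gy[:, :, i::s, j::s],
                                               optimize=True)
            w._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for i in range(s):
                for j in range(s):
                    gx += np.einsum("nohw,co->nchw", gy[:, :, i::s, j::s],
                                    wd[:, :, i, j], optimize=True)
            x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params, seen = [], set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def modules(self):
        mods = [self]

        def collect(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        for v in vars(self).values():
            collect(v)
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat state for checkpointing --------------------------------------
    def state_arrays(self):
        """Ordered list of all parameter and buffer arrays (views)."""
        arrays = []
        for m in self.modules():
            for k in sorted(vars(m)):
                v = vars(m)[k]
                if isinstance(v, Parameter):
                    arrays.append(v.data)
                elif isinstance(v, np.ndarray):
                    arrays.append(v)
        return arrays

    def load_state_arrays(self, arrays):
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(f"state length mismatch: {len(own)} vs {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != np.asarray(src).shape:
                raise ValueError(f"shape mismatch: {dst.shape} vs {np.shape(src)}")
            dst[...] = src


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel_size, stride=1, padding=0,
                 groups=1, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = (in_ch // groups) * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, (out_ch, in_ch // groups, k, k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)


class ConvTranspose2d(Module):
    def __init__(self, in_ch, out_ch, stride=2, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_ch)
        self.weight = Parameter(rng.normal(0.0, scale, (in_ch, out_ch, stride, stride)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride

    def __call__(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    """Batch normalisation with running statistics.

    `momentum` is the retention factor of the running average
    (running = momentum * running + (1 - momentum) * batch).
    """

    def __init__(self, num_ch, eps=1e-3, momentum=0.99):
        super().__init__()
        self.gamma = Parameter(np.ones((1, num_ch, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_ch, 1, 1)))
        self.running_mean = np.zeros((1, num_ch, 1, 1))
        self.running_var = np.ones((1, num_ch, 1, 1))
        self.eps, self.momentum = eps, momentum

    def __call__(self, x):
        if not self.training:
            xn = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
            return self.gamma * xn + self.beta

        # fused training-mode primitive (one backward for the whole block)
        axes = (0, 2, 3)
        d = x.data
        mu = d.mean(axis=axes, keepdims=True)
        xc = d - mu
        var = np.mean(xc * xc, axis=axes, keepdims=True)
        self.running_mean[...] = (self.momentum * self.running_mean
                                  + (1 - self.momentum) * mu)
        self.running_var[...] = (self.momentum * self.running_var
                                 + (1 - self.momentum) * var)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xn = xc * inv_std
        gamma, beta = self.gamma, self.beta
        out_data = gamma.data * xn + beta.data

        def backward(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes, keepdims=True))
            if gamma.requires_grad:
                gamma._accum((g * xn).sum(axis=axes, keepdims=True))
            if x.requires_grad:
                gn = g * gamma.data
                m1 = gn.mean(axis=axes, keepdims=True)
                m2 = (gn * xn).mean(axis=axes, keepdims=True)
                x._accum(inv_std * (gn - m1 - xn * m2))

        return Tensor._make(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled-from-schedule lr (passed per step) and L2 decay."""

    def __init__(self, params, weight_decay=0.0, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = list(params)
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p.data -= lr * mh / (np.sqrt(vh) + self.eps)
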