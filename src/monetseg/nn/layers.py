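"""Minimal CNN layer library with explicit backprop.

Layers operate on NCHW float arrays. Each leaf layer caches what its
backward pass needs during ``forward(training=True)`` and accumulates
parameter gradients in ``self.grads``. Composites wire layers together and
propagate gradients in reverse. Parameter enumeration (``named_tensors``)
is deterministic and includes non-trainable normalization statistics, which
is what the parameter accounting in this package counts.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
from scipy.special import expit


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _same_pad(size, kernel, stride, dilation):
    """Asymmetric 'same' padding (begin, end) so out = ceil(size/stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + (kernel - 1) * dilation + 1 - size, 0)
    return total // 2, total - total // 2


def _im2col(xp, kh, kw, stride, dilation, oh, ow):
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            r = i * dilation
            q = j * dilation
            cols[:, :, i, j] = xp[:, :, r:r + (oh - 1) * stride + 1:stride,
                                  q:q + (ow - 1) * stride + 1:stride]
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(dcols, xp_shape, kh, kw, stride, dilation, oh, ow):
    n, c, hp, wp = xp_shape
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            r = i * dilation
            q = j * dilation
            dxp[:, :, r:r + (oh - 1) * stride + 1:stride,
                q:q + (ow - 1) * stride + 1:stride] += d6[:, :, i, j]
    return dxp


class Layer:
    """Base layer: parameter/buffer bookkeeping plus forward/backward."""

    _params: tuple = ()
    _buffers: tuple = ()

    def __init__(self):
        self.grads: dict[str, np.ndarray] = {}
        self.capture = False
        self.last_output = None

    # -- structure ---------------------------------------------------------
    def children(self):
        return ()

    def named_tensors(self, prefix=""):
        """Yield (name, array, trainable) for every registered tensor."""
        for name in self._params:
            yield prefix + name, getattr(self, name), True
        for name in self._buffers:
            yield prefix + name, getattr(self, name), False
        for cname, child in self.children():
            yield from child.named_tensors(prefix + cname + ".")

    def named_param_layers(self, prefix=""):
        """Yield (name, layer, attr) for every trainable parameter."""
        for name in self._params:
            yield prefix + name, self, name
        for cname, child in self.children():
            yield from child.named_param_layers(prefix + cname + ".")

    def modules(self, prefix=""):
        yield prefix.rstrip("."), self
        for cname, child in self.children():
            yield from child.modules(prefix + cname + ".")

    def zero_grad(self):
        for _, layer in self.modules():
            layer.grads = {}

    def state_dict(self):
        return OrderedDict((n, a.copy()) for n, a, _ in self.named_tensors())

    def load_state_dict(self, state):
        for name, _, _ in self.named_tensors():
            if name not in state:
                raise KeyError(f"missing tensor {name!r}")
        for name, layer, attr in self._tensor_layers():
            src = np.asarray(state[name])
            dst = getattr(layer, attr)
            if src.shape != dst.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: {src.shape} vs {dst.shape}")
            setattr(layer, attr, src.astype(dst.dtype, copy=True))

    def _tensor_layers(self, prefix=""):
        for name in self._params + self._buffers:
            yield prefix + name, self, name
        for cname, child in self.children():
            yield from child._tensor_layers(prefix + cname + ".")

    # -- compute -----------------------------------------------------------
    def forward(self, x, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover
        raise NotImplementedError

    def _record(self, out):
        if self.capture:
            self.last_output = out.copy()
        return out

    def __call__(self, x, training=False, rng=None):
        return self.forward(x, training=training, rng=rng)


class Conv2d(Layer):
    """2D convolution (cross-correlation) with 'same' padding by default."""

    _params = ("weight", "bias")

    def __init__(self, in_channels, out_channels, kernel=3, stride=1,
                 dilation=1, padding="same", dtype=np.float32):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _pair(kernel)
        self.stride = stride
        self.dilation = dilation
        self.padding = padding
        kh, kw = self.kernel
        self.weight = np.zeros((out_channels, in_channels, kh, kw), dtype=dtype)
        self.bias = np.zeros(out_channels, dtype=dtype)
        self._cache = None

    def _pads(self, h, w):
        kh, kw = self.kernel
        if self.padding == "same":
            return (_same_pad(h, kh, self.stride, self.dilation),
                    _same_pad(w, kw, self.stride, self.dilation))
        p = int(self.padding)
        return (p, p), (p, p)

    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        kh, kw = self.kernel
        (pt, pb), (pl, pr) = self._pads(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        hp, wp = xp.shape[2:]
        oh = (hp - (kh - 1) * self.dilation - 1) // self.stride + 1
        ow = (wp - (kw - 1) * self.dilation - 1) // self.stride + 1
        cols = _im2col(xp, kh, kw, self.stride, self.dilation, oh, ow)
        w2 = self.weight.reshape(self.out_channels, -1)
        out = np.matmul(w2, cols) + self.bias[:, None]
        out = out.reshape(n, self.out_channels, oh, ow)
        if training:
            self._cache = (xp, (pt, pb, pl, pr), oh, ow)
        return self._record(out)

    def backward(self, grad):
        xp, (pt, pb, pl, pr), oh, ow = self._cache
        n = grad.shape[0]
        kh, kw = self.kernel
        cols = _im2col(xp, kh, kw, self.stride, self.dilation, oh, ow)
        g2 = grad.reshape(n, self.out_channels, oh * ow)
        dw = np.einsum("nop,nkp->ok", g2, cols, optimize=True)
        self.grads["weight"] = self.grads.get("weight", 0) + \
            dw.reshape(self.weight.shape)
        self.grads["bias"] = self.grads.get("bias", 0) + g2.sum(axis=(0, 2))
        w2 = self.weight.reshape(self.out_channels, -1)
        dcols = np.matmul(w2.T, g2)
        dxp = _col2im(dcols, xp.shape, kh, kw, self.stride, self.dilation,
                      oh, ow)
        hp, wp = xp.shape[2:]
        return dxp[:, :, pt:hp - pb or None, pl:wp - pr or None]


class ConvTranspose2d(Layer):
    """Stride-s transposed convolution realised as zero-insertion + conv.

    Output spatial size is exactly ``stride`` times the input size, matching
    the 'same'-padded decoder contract of the architectures here.
    """

    _params = ("weight", "bias")

    def __init__(self, in_channels, out_channels, kernel=2, stride=2,
                 dtype=np.float32):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _pair(kernel)
        self.stride = stride
        kh, kw = self.kernel
        self.weight = np.zeros((out_channels, in_channels, kh, kw), dtype=dtype)
        self.bias = np.zeros(out_channels, dtype=dtype)
        self._cache = None

    def _geometry(self, h, w):
        s = self.stride
        kh, kw = self.kernel
        th, tw = kh + s - 2, kw + s - 2   # total pad so out = s * in
        return (th // 2, th - th // 2), (tw // 2, tw - tw // 2)

    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        s = self.stride
        kh, kw = self.kernel
        up = np.zeros((n, c, (h - 1) * s + 1, (w - 1) * s + 1), dtype=x.dtype)
        up[:, :, ::s, ::s] = x
        (pt, pb), (pl, pr) = self._geometry(h, w)
        xp = np.pad(up, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        oh, ow = h * s, w * s
        cols = _im2col(xp, kh, kw, 1, 1, oh, ow)
        w2 = self.weight.reshape(self.out_channels, -1)
        out = (np.matmul(w2, cols) + self.bias[:, None]).reshape(
            n, self.out_channels, oh, ow)
        if training:
            self._cache = (xp, (pt, pb, pl, pr), h, w, oh, ow)
        return self._record(out)

    def backward(self, grad):
        xp, (pt, pb, pl, pr), h, w, oh, ow = self._cache
        n = grad.shape[0]
        s = self.stride
        kh, kw = self.kernel
        cols = _im2col(xp, kh, kw, 1, 1, oh, ow)
        g2 = grad.reshape(n, self.out_channels, oh * ow)
        dw = np.einsum("nop,nkp->ok", g2, cols, optimize=True)
        self.grads["weight"] = self.grads.get("weight", 0) + \
            dw.reshape(self.weight.shape)
        self.grads["bias"] = self.grads.get("bias", 0) + g2.sum(axis=(0, 2))
        w2 = self.weight.reshape(self.out_channels, -1)
        dcols = np.matmul(w2.T, g2)
        dxp = _col2im(dcols, xp.shape, kh, kw, 1, 1, oh, ow)
        hp, wp = xp.shape[2:]
        dup = dxp[:, :, pt:hp - pb or None, pl:wp - pr or None]
        return dup[:, :, ::s, ::s]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Running mean/var are registered buffers and therefore count toward the
    parameter totals, at 4 parameters per channel together with scale/shift.
    """

    _params = ("gamma", "beta")
    _buffers = ("running_mean", "running_var")

    def __init__(self, channels, momentum=0.9, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x, training=False, rng=None):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (m * self.running_mean +
                                 (1 - m) * mean).astype(x.dtype)
            self.running_var = (m * self.running_var +
                                (1 - m) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * ivar[:, None, None]
        out = self.gamma[:, None, None] * xhat + self.beta[:, None, None]
        if training:
            self._cache = (xhat, ivar)
        return self._record(out)

    def backward(self, grad):
        xhat, ivar = self._cache
        n_el = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dxhat = grad * self.gamma[:, None, None]
        self.grads["gamma"] = self.grads.get("gamma", 0) + \
            (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = self.grads.get("beta", 0) + grad.sum(axis=(0, 2, 3))
        s1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        dx = (ivar[:, None, None] / n_el) * (n_el * dxhat - s1 - xhat * s2)
        return dx.astype(grad.dtype)


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def __init__(self, alpha=1.0):
        super().__init__()
        self.alpha = alpha
        self._cache = None

    def forward(self, x, training=False, rng=None):
        neg = self.alpha * np.expm1(np.minimum(x, 0))
        out = np.where(x > 0, x, neg).astype(x.dtype)
        if training:
            self._cache = (x > 0, neg)
        return self._record(out)

    def backward(self, grad):
        pos, neg = self._cache
        return grad * np.where(pos, 1.0, neg + self.alpha).astype(grad.dtype)


class SpatialDropout2d(Layer):
    """Drops whole feature channels at rate p during training."""

    def __init__(self, p=0.1):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0:
            self._mask = None
            return self._record(x)
        if rng is None:
            raise ValueError("spatial dropout in training mode needs an rng")
        keep = (rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.p)
        self._mask = keep.astype(x.dtype) / (1.0 - self.p)
        return self._record(x * self._mask)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling; parameter-free."""

    def __init__(self, size=2):
        super().__init__()
        self.size = size
        self._cache = None

    def forward(self, x, training=False, rng=None):
        s = self.size
        n, c, h, w = x.shape
        if h % s or w % s:
            raise ValueError("spatial size must be divisible by pool size")
        v = x.reshape(n, c, h // s, s, w // s, s)
        v = v.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // s, w // s, s * s)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return self._record(out)

    def backward(self, grad):
        idx, (n, c, h, w) = self._cache
        s = self.size
        dv = np.zeros((n, c, h // s, w // s, s * s), dtype=grad.dtype)
        np.put_along_axis(dv, idx[..., None], grad[..., None], axis=-1)
        dv = dv.reshape(n, c, h // s, w // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        return dv.reshape(n, c, h, w)


class Sigmoid(Layer):
    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x, training=False, rng=None):
        out = expit(x).astype(x.dtype)
        if training:
            self._cache = out
        return self._record(out)

    def backward(self, grad):
        y = self._cache
        return grad * y * (1.0 - y)


class Sequential(Layer):
    def __init__(self, *layers, names=None):
        super().__init__()
        self.layers = list(layers)
        self.names = list(names) if names else [str(i) for i in
                                                range(len(self.layers))]

    def children(self):
        return list(zip(self.names, self.layers))

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return self._record(x)

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
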