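"""A compact numpy neural-network core with exact hand-written gradients.

Sized for desk-scale survival cohorts (tens to hundreds of patients,
16x16-ish images): every layer implements ``forward``/``backward`` with
cached intermediates, convolutions go through ``sliding_window_view``
im2col, and the ConvLSTM performs full backpropagation through time.
Everything is float64 and fully deterministic given the rng handed to the
model, which makes training runs bit-reproducible.

Array conventions: dense activations are (N, F); convolutional
activations are (N, C, H, W); sequences are (N, T, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(x, k):
    """(N, C, H, W) -> (N*H*W, C*k*k) patches for stride-1 'same' conv."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    n, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def conv2d_forward(x, weight, bias):
    """Stride-1 'same' 2D convolution. weight: (cout, cin, k, k)."""
    n, c, h, w = x.shape
    cout, cin, k, _ = weight.shape
    cols = _im2col(x, k)
    out = cols @ weight.reshape(cout, -1).T + bias
    return out.reshape(n, h, w, cout).transpose(0, 3, 1, 2)


def conv2d_backward(dout, x, weight):
    """Gradients of conv2d_forward w.r.t. x, weight and bias."""
    n, c, h, w = x.shape
    cout, cin, k, _ = weight.shape
    p = k // 2
    rows = dout.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
    cols = _im2col(x, k)
    dweight = (rows.T @ cols).reshape(weight.shape)
    dbias = rows.sum(axis=0)
    dcols = (rows @ weight.reshape(cout, -1)).reshape(n, h, w, c, k, k)
    dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, H, W, k, k)
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj]
    return dxp[:, :, p:p + h, p:p + w], dweight, dbias


class Layer:
    """Base layer: parameter dicts plus cached-state forward/backward."""

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    def penalty(self) -> float:
        return 0.0


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        scale = np.sqrt(6.0 / (n_in + n_out))
        self.params = {"w": rng.uniform(-scale, scale, size=(n_in, n_out)),
                       "b": np.zeros(n_out)}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"w": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["w"].T


class Conv2D(Layer):
    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        fan = c_in * kernel * kernel
        scale = np.sqrt(6.0 / (fan + c_out * kernel * kernel))
        self.params = {"w": rng.uniform(-scale, scale, size=(c_out, c_in, kernel, kernel)),
                       "b": np.zeros(c_out)}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return conv2d_forward(x, self.params["w"], self.params["b"])

    def backward(self, dout):
        dx, dw, db = conv2d_backward(dout, self._x, self.params["w"])
        self.grads = {"w": dw, "b": db}
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2D(Layer):
    """2x2, stride 2; spatial dims must be even."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2D needs even spatial dims, got {(h, w)}")
        self._shape = x.shape
        xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h // 2, w // 2, 4))
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        return (dxr.reshape(n, c, h // 2, w // 2, 2, 2)
                   .transpose(0, 1, 2, 4, 3, 5)
                   .reshape(n, c, h, w))


class GlobalAvgPool2D(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class BatchNorm(Layer):
    """Normalizes over the batch (and spatial axes for conv activations).

    Training uses batch statistics and updates exponential running
    moments; inference uses the running moments, so inference output is a
    deterministic function of the weights and input.
    """

    def __init__(self, n_features, momentum=0.9, eps=1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def _axes_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, -1)
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        raise ValueError(f"BatchNorm supports 2D or 4D input, got ndim={x.ndim}")

    def forward(self, x, train=False, rng=None):
        axes, shape = self._axes_shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._train = train
        self._axes, self._shape = axes, shape
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) / self._std.reshape(shape)
        return self.params["gamma"].reshape(shape) * self._xhat + self.params["beta"].reshape(shape)

    def backward(self, dout):
        axes, shape = self._axes, self._shape
        self.grads = {"gamma": (dout * self._xhat).sum(axis=axes),
                      "beta": dout.sum(axis=axes)}
        g = self.params["gamma"].reshape(shape)
        if not self._train:
            return dout * g / self._std.reshape(shape)
        m = dout.size / dout.shape[1] if dout.ndim == 4 else dout.shape[0]
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=axes).reshape(shape)
              - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shape))
        return dx / self._std.reshape(shape)


class Dropout(Layer):
    def __init__(self, rate):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class ActivityL2(Layer):
    """Identity layer adding an L2 activity penalty ``lam * mean(x**2)``."""

    def __init__(self, lam):
        super().__init__()
        self.lam = lam

    def forward(self, x, train=False, rng=None):
        self._x = x if train else None
        self._penalty = self.lam * float(np.mean(x * x)) if train else 0.0
        return x

    def backward(self, dout):
        if self._x is None or self.lam == 0:
            return dout
        return dout + 2.0 * self.lam * self._x / self._x.size

    def penalty(self):
        return self._penalty


class ConvLSTM2D(Layer):
    """Convolutional LSTM over (N, T, C, H, W) with full BPTT.

    Gates are a single stride-1 'same' convolution of the concatenated
    (input, hidden) stack into 4*F channels (input, forget, cell, output
    order); the forget-gate bias starts at 1. ``return_sequences`` selects
    between the full hidden sequence and the final hidden state.
    """

    def __init__(self, c_in, n_filters, kernel, rng, return_sequences=False):
        super().__init__()
        self.f = n_filters
        self.k = kernel
        self.return_sequences = return_sequences
        fan = (c_in + n_filters) * kernel * kernel
        scale = np.sqrt(6.0 / (fan + 4 * n_filters * kernel * kernel))
        bias = np.zeros(4 * n_filters)
        bias[n_filters:2 * n_filters] = 1.0  # forget-gate bias
        self.params = {
            "w": rng.uniform(-scale, scale, size=(4 * n_filters, c_in + n_filters, kernel, kernel)),
            "b": bias,
        }

    def forward(self, x, train=False, rng=None):
        n, t, c, h, w = x.shape
        f = self.f
        hid = np.zeros((n, f, h, w))
        cell = np.zeros((n, f, h, w))
        self._caches = []
        outs = []
        for step in range(t):
            xh = np.concatenate([x[:, step], hid], axis=1)
            z = conv2d_forward(xh, self.params["w"], self.params["b"])
            gi = _sigmoid(z[:, :f])
            gf = _sigmoid(z[:, f:2 * f])
            gg = np.tanh(z[:, 2 * f:3 * f])
            go = _sigmoid(z[:, 3 * f:])
            cell_new = gf * cell + gi * gg
            tanh_c = np.tanh(cell_new)
            hid = go * tanh_c
            self._caches.append((xh, gi, gf, gg, go, cell, tanh_c))
            cell = cell_new
            if self.return_sequences:
                outs.append(hid)
        self._in_shape = x.shape
        return np.stack(outs, axis=1) if self.return_sequences else hid

    def backward(self, dout):
        n, t, c_total, h, w = (*self._in_shape[:2], self._in_shape[2],
                               self._in_shape[3], self._in_shape[4])
        f = self.f
        c_in = c_total
        dx = np.zeros(self._in_shape)
        dw = np.zeros_like(self.params["w"])
        db = np.zeros_like(self.params["b"])
        dh_carry = np.zeros((n, f, h, w))
        dc_carry = np.zeros((n, f, h, w))
        for step in range(t - 1, -1, -1):
            xh, gi, gf, gg, go, cell_prev, tanh_c = self._caches[step]
            if self.return_sequences:
                dh = dh_carry + dout[:, step]
            else:
                dh = dh_carry + (dout if step == t - 1 else 0.0)
            dc = dc_carry + dh * go * (1.0 - tanh_c ** 2)
            dgo = dh * tanh_c
            dgi = dc * gg
            dgf = dc * cell_prev
            dgg = dc * gi
            dc_carry = dc * gf
            dz = np.concatenate([
                dgi * gi * (1 - gi),
                dgf * gf * (1 - gf),
                dgg * (1 - gg ** 2),
                dgo * go * (1 - go),
            ], axis=1)
            dxh, dw_t, db_t = conv2d_backward(dz, xh, self.params["w"])
            dw += dw_t
            db += db_t
            dx[:, step] = dxh[:, :c_in]
            dh_carry = dxh[:, c_in:]
        self.grads = {"w": dw, "b": db}
        return dx


class TimeDistributed(Layer):
    """Apply a (N, ...)-shaped layer to every timestep of (N, T, ...)."""

    def __init__(self, inner: Layer):
        super().__init__()
        self.inner = inner

    @property
    def params(self):
        return self.inner.params

    @params.setter
    def params(self, value):  # Layer.__init__ assigns {}; delegate afterwards
        if value:
            self.inner.params = value

    @property
    def grads(self):
        return self.inner.grads

    @grads.setter
    def grads(self, value):
        if value:
            self.inner.grads = value

    def forward(self, x, train=False, rng=None):
        self._nt = x.shape[:2]
        out = self.inner.forward(x.reshape(-1, *x.shape[2:]), train=train, rng=rng)
        return out.reshape(*self._nt, *out.shape[1:])

    def backward(self, dout):
        dx = self.inner.backward(dout.reshape(-1, *dout.shape[2:]))
        return dx.reshape(*self._nt, *dx.shape[1:])

    def penalty(self):
        return self.inner.penalty()


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def penalty(self):
        return sum(layer.penalty() for layer in self.layers)

    def iter_params(self):
        for i, layer in enumerate(self.layers):
            inner = layer.inner if isinstance(layer, TimeDistributed) else layer
            for name, arr in inner.params.items():
                yield f"{i}.{type(inner).__name__}.{name}", inner, name
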