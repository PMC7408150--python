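"""Minimal numpy neural-network engine.

Implements exactly the layer vocabulary the GAN/CAE architectures need:
2-D convolution (zero or reflection padding), strided transposed
convolution, dense layers, batch/instance normalization, max-pooling,
nearest-neighbour upsampling, dropout, and the usual activations, all
with hand-derived backward passes, plus an Adam optimizer with optional
decoupled L2 weight penalty and per-step learning-rate override.

Conventions: tensors are float32 NCHW; every layer caches what its own
backward pass needs from the *most recent* forward call, so when a
network appears several times in one objective (e.g. a cycle
G_A(G_B(a))) each term is forwarded and backpropagated immediately,
accumulating gradients before a single optimizer step.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, oh*ow) patch matrix (copies)."""
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    shape = (n, c, kh, kw, oh, ow)
    strides = (sn, sc, sh, sw, sh * stride, sw * stride)
    cols = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, oh * ow)


def _col2im(dcols: np.ndarray, padded_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    """Scatter-add inverse of _im2col back onto the padded input shape."""
    n, c, h, w = padded_shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    dx = np.zeros(padded_shape, dtype=_F32)
    d6 = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += d6[:, :, i, j]
    return dx


# ---------------------------------------------------------------------------
# Layer base
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: `params`/`grads` dicts plus forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        # parameter names subject to L2 weight penalty (kernels only)
        self.decayed: set[str] = set()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, st: dict[str, np.ndarray]):
        for k, v in st.items():
            self.params[k] = v.copy()


class Conv2d(Layer):
    """3x3/4x4/... convolution with 'same'-style integer padding.

    padding_mode 'zeros' or 'reflect' (reflection is the CycleGAN
    generator convention; avoids border artifacts).
    """

    def __init__(self, cin, cout, k, stride=1, pad=None, padding_mode="zeros",
                 rng=None, init_std=None, bias=True):
        super().__init__()
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        if pad is None:
            pad = (k - 1) // 2
        # pad: int (symmetric) or (before, after) per spatial axis —
        # even kernels need asymmetric padding for 'same' output sizes
        self.pad = (pad, pad) if np.isscalar(pad) else tuple(pad)
        self.padding_mode = padding_mode
        rng = rng or np.random.default_rng()
        if init_std is None:  # He init for ReLU-ish nets
            init_std = np.sqrt(2.0 / (cin * k * k))
        self.params["W"] = rng.normal(0.0, init_std, (cout, cin, k, k)).astype(_F32)
        self.decayed.add("W")
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(cout, dtype=_F32)
        self.zero_grad()

    def _pad(self, x):
        p0, p1 = self.pad
        if p0 == 0 and p1 == 0:
            return x
        mode = "reflect" if self.padding_mode == "reflect" else "constant"
        return np.pad(x, ((0, 0), (0, 0), (p0, p1), (p0, p1)), mode=mode)

    def forward(self, x, train=True):
        x = x.astype(_F32, copy=False)
        xp = self._pad(x)
        self._padded_shape = xp.shape
        self._in_shape = x.shape
        cols = _im2col(xp, self.k, self.k, self.stride)
        self._cols = cols
        n = x.shape[0]
        wmat = self.params["W"].reshape(self.cout, -1)
        y = np.einsum("oc,ncp->nop", wmat, cols, optimize=True)
        if self.use_bias:
            y += self.params["b"][None, :, None]
        oh = (self._padded_shape[2] - self.k) // self.stride + 1
        ow = (self._padded_shape[3] - self.k) // self.stride + 1
        return y.reshape(n, self.cout, oh, ow)

    def backward(self, dy):
        n, _, oh, ow = dy.shape
        dyf = dy.reshape(n, self.cout, oh * ow).astype(_F32, copy=False)
        self.grads["W"] += np.einsum("nop,ncp->oc", dyf, self._cols,
                                     optimize=True).reshape(self.params["W"].shape)
        if self.use_bias:
            self.grads["b"] += dyf.sum(axis=(0, 2))
        wmat = self.params["W"].reshape(self.cout, -1)
        dcols = np.einsum("oc,nop->ncp", wmat, dyf, optimize=True)
        dxp = _col2im(dcols, self._padded_shape, self.k, self.k, self.stride)
        p0, p1 = self.pad
        if p0 == 0 and p1 == 0:
            return dxp
        if self.padding_mode == "reflect":
            assert p0 == p1, "reflection padding requires symmetric pad"
            p = p0
            # fold reflected borders back onto their interior sources
            h, w = self._in_shape[2], self._in_shape[3]
            core = dxp[:, :, p:p + h, p:p + w].copy()
            for i in range(p):
                core[:, :, p - i, :] += dxp[:, :, i, p:p + w]
                core[:, :, h - 1 - (p - i), :] += dxp[:, :, p + h + (p - 1 - i), p:p + w]
            tmp = np.zeros_like(core)
            for j in range(p):
                tmp[:, :, :, p - j] += dxp[:, :, p:p + h, j]
                tmp[:, :, :, w - 1 - (p - j)] += dxp[:, :, p:p + h, p + w + (p - 1 - j)]
            # corners were counted through rows above only for the row fold;
            # column folds of the (already folded) corner strips:
            core += tmp
            for i in range(p):
                for j in range(p):
                    core[:, :, p - i, p - j] += dxp[:, :, i, j]
                    core[:, :, p - i, w - 1 - (p - j)] += dxp[:, :, i, p + w + (p - 1 - j)]
                    core[:, :, h - 1 - (p - i), p - j] += dxp[:, :, p + h + (p - 1 - i), j]
                    core[:, :, h - 1 - (p - i), w - 1 - (p - j)] += \
                        dxp[:, :, p + h + (p - 1 - i), p + w + (p - 1 - j)]
            return core
        return dxp[:, :, p0:p0 + self._in_shape[2], p0:p0 + self._in_shape[3]]


class ConvTranspose2d(Layer):
    """Stride-s transposed convolution via zero-dilation + unit-stride conv.

    With kernel k, stride s and pad p the output side is s*H for the
    (k=4, s=2, p=1) and (k=3, s=2, p=1, output_padding=1) configurations
    used by the GAN decoders.
    """

    def __init__(self, cin, cout, k, stride=2, pad=1, rng=None, init_std=None):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        rng = rng or np.random.default_rng()
        if init_std is None:
            init_std = np.sqrt(2.0 / (cin * k * k))
        self.params["W"] = rng.normal(0.0, init_std, (cout, cin, k, k)).astype(_F32)
        self.params["b"] = np.zeros(cout, dtype=_F32)
        self.decayed.add("W")
        self.zero_grad()

    def _dilate_pad(self, x):
        n, c, h, w = x.shape
        s, k, p = self.stride, self.k, self.pad
        # output target: s*h; unit-stride conv output = dil + 2*edge + extra - k + 1
        dil_h = (h - 1) * s + 1
        dil_w = (w - 1) * s + 1
        edge = k - 1 - p
        extra = s * h - (dil_h + 2 * edge - k + 1)  # trailing output padding
        xd = np.zeros((n, c, dil_h + 2 * edge + extra, dil_w + 2 * edge + extra), dtype=_F32)
        xd[:, :, edge:edge + dil_h:s, edge:edge + dil_w:s] = x
        self._edge, self._extra, self._dil = edge, extra, (dil_h, dil_w)
        return xd

    def forward(self, x, train=True):
        x = x.astype(_F32, copy=False)
        self._in_shape = x.shape
        xd = self._dilate_pad(x)
        self._padded_shape = xd.shape
        cols = _im2col(xd, self.k, self.k, 1)
        self._cols = cols
        n = x.shape[0]
        wmat = self.params["W"].reshape(self.cout, -1)
        y = np.einsum("oc,ncp->nop", wmat, cols, optimize=True)
        y += self.params["b"][None, :, None]
        oh = self._padded_shape[2] - self.k + 1
        ow = self._padded_shape[3] - self.k + 1
        return y.reshape(n, self.cout, oh, ow)

    def backward(self, dy):
        n, _, oh, ow = dy.shape
        dyf = dy.reshape(n, self.cout, oh * ow).astype(_F32, copy=False)
        self.grads["W"] += np.einsum("nop,ncp->oc", dyf, self._cols,
                                     optimize=True).reshape(self.params["W"].shape)
        self.grads["b"] += dyf.sum(axis=(0, 2))
        wmat = self.params["W"].reshape(self.cout, -1)
        dcols = np.einsum("oc,nop->ncp", wmat, dyf, optimize=True)
        dxd = _col2im(dcols, self._padded_shape, self.k, self.k, 1)
        e, s = self._edge, self.stride
        dil_h, dil_w = self._dil
        return dxd[:, :, e:e + dil_h:s, e:e + dil_w:s]


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None, init_std=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if init_std is None:
            init_std = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, init_std, (n_in, n_out)).astype(_F32)
        self.params["b"] = np.zeros(n_out, dtype=_F32)
        self.decayed.add("W")
        self.zero_grad()

    def forward(self, x, train=True):
        self._x = x.astype(_F32, copy=False)
        return self._x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        dy = dy.astype(_F32, copy=False)
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape  # per-sample shape

    def forward(self, x, train=True):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._in)


class BatchNorm(Layer):
    """Batch normalization over (N,) or (N,H,W) per channel; NCHW or (N,F)."""

    def __init__(self, c, momentum=0.9, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=_F32)
        self.params["beta"] = np.zeros(c, dtype=_F32)
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.zero_grad()

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _bc(self, v, x):
        return v if x.ndim == 2 else v[None, :, None, None]

    def forward(self, x, train=True):
        x = x.astype(_F32, copy=False)
        ax = self._axes(x)
        if train:
            mu = x.mean(axis=ax)
            var = x.var(axis=ax)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - self._bc(mu, x)) * self._bc(self._inv, x)
        self._train = train
        return self._bc(self.params["gamma"], x) * self._xhat + self._bc(self.params["beta"], x)

    def backward(self, dy):
        dy = dy.astype(_F32, copy=False)
        ax = self._axes(dy)
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (dy * xhat).sum(axis=ax)
        self.grads["beta"] += dy.sum(axis=ax)
        g = self._bc(self.params["gamma"], dy)
        if not self._train:
            return dy * g * self._bc(inv, dy)
        dxhat = dy * g
        t = dxhat - dxhat.mean(axis=ax, keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=ax, keepdims=True)
        return t * self._bc(inv, dy)


class InstanceNorm2d(Layer):
    """Per-sample per-channel normalization over (H,W) with affine params."""

    def __init__(self, c, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(c, dtype=_F32)
        self.params["beta"] = np.zeros(c, dtype=_F32)
        self.zero_grad()

    def forward(self, x, train=True):
        x = x.astype(_F32, copy=False)
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.params["gamma"][None, :, None, None] * self._xhat \
            + self.params["beta"][None, :, None, None]

    def backward(self, dy):
        dy = dy.astype(_F32, copy=False)
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.params["gamma"][None, :, None, None]
        t = dxhat - dxhat.mean(axis=(2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return t * inv


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(_F32, copy=False)

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(_F32, copy=False)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x).astype(_F32, copy=False)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = (1.0 / (1.0 + np.exp(-x))).astype(_F32, copy=False)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling (spatial dims must be even)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        mask = (xr == y[:, :, :, None, :, None])
        # break ties: keep only the first max per 2x2 window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._shape = x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        d = self._mask * dy[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class Upsample2d(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    def __init__(self, p=0.5, rng=None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=True):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(_F32, copy=False)

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Residual(Layer):
    """y = x + body(x); the CycleGAN residual block wraps a Sequential body."""

    def __init__(self, body: "Sequential"):
        super().__init__()
        self.body = body

    def forward(self, x, train=True):
        return x + self.body.forward(x, train=train)

    def backward(self, dy):
        return dy + self.body.backward(dy)

    # parameter plumbing delegates to the body
    def layers_flat(self):
        return self.body.layers_flat()

    def zero_grad(self):
        self.body.zero_grad()

    def state(self):
        return self.body.state()

    def load_state(self, st):
        self.body.load_state(st)


class Sequential:
    """Ordered layer container with chained forward/backward."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def __call__(self, x, train=True):
        return self.forward(x, train=train)

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def layers_flat(self):
        out = []
        for l in self.layers:
            if isinstance(l, Residual):
                out.extend(l.layers_flat())
            else:
                out.append(l)
        return out

    def zero_grad(self):
        for l in self.layers_flat():
            l.zero_grad()

    def n_params(self):
        return sum(p.size for l in self.layers_flat() for p in l.params.values())

    def state(self):
        return [l.state() for l in self.layers_flat()]

    def load_state(self, st):
        for l, s in zip(self.layers_flat(), st):
            l.load_state(s)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam over one or more Sequential networks.

    `weight_decay` adds lam*W to the gradient of kernel parameters
    (classic L2 penalty, matching an L2-norm regularizer on conv weights).
    """

    def __init__(self, nets, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        if isinstance(nets, Sequential):
            nets = [nets]
        self.nets = nets
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m, self.v = [], []
        for l in self._layers():
            self.m.append({k: np.zeros_like(p) for k, p in l.params.items()})
            self.v.append({k: np.zeros_like(p) for k, p in l.params.items()})

    def _layers(self):
        for net in self.nets:
            yield from net.layers_flat()

    def zero_grad(self):
        for net in self.nets:
            net.zero_grad()

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for i, l in enumerate(self._layers()):
            for k, p in l.params.items():
                g = l.grads[k]
                if self.weight_decay and k in l.decayed:
                    g = g + self.weight_decay * p
                m = self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                v = self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Losses (return (scalar, dL/dpred))
# ---------------------------------------------------------------------------

def mse_loss(pred, target):
    diff = (pred - target).astype(_F32, copy=False)
    return float(np.mean(diff ** 2)), (2.0 / diff.size) * diff


def l1_loss(pred, target):
    diff = (pred - target).astype(_F32, copy=False)
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def bce_loss(p, target, eps=1e-7):
    """Binary cross-entropy on probabilities with epsilon clamping."""
    p = np.clip(p, eps, 1 - eps)
    loss = float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))
    grad = (-(target / p) + (1 - target) / (1 - p)) / p.size
    return loss, grad


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits, labels):
    """Categorical cross-entropy from logits; labels are int class ids."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.clip(p[np.arange(n), labels], 1e-12, None))))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
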