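"""Minimal CPU neural-network engine used by the counting models.

Implements exactly the pieces the architectures need — 3x3/1x1 "same"
convolutions, 2x2 max-pooling, nearest-neighbour upsampling, batch
normalization, dropout, dense layers, leaky ReLU / ReLU / sigmoid
activations — with hand-derived backward passes and an Adam optimizer.
Tensors are NHWC (batch, height, width, channels), float32 by default.

Every layer exposes ``forward(x, training)`` and ``backward(dy)``;
``backward`` returns the gradient w.r.t. the input and fills
``layer.grads`` for each entry of ``layer.params``. Gradient correctness
is asserted against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


# ---------------------------------------------------------------------------
# weight initializers (seeded, Keras-compatible conventions)
# ---------------------------------------------------------------------------

def glorot_uniform(shape, fan_in, fan_out, rng, dtype=DTYPE):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(shape, rng, gain=1.0, dtype=DTYPE):
    """Orthogonal init: flatten all but the last axis, orthogonalize via QR."""
    flat = (int(np.prod(shape[:-1])), shape[-1])
    a = rng.standard_normal(size=(max(flat), min(flat)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # uniform Haar measure
    if flat[0] < flat[1]:
        q = q.T
    return (gain * q[: flat[0], : flat[1]]).reshape(shape).astype(dtype)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: parameter dict, gradient dict, trainable flag."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def sublayers(self):
        return [self]


class Conv2D(Layer):
    """Stride-1 'same' convolution with a 3x3 or 1x1 kernel.

    Weight shape (k, k, in_ch, out_ch). The forward pass builds sliding
    windows over the zero-padded input and contracts them against the
    kernel with a single BLAS call; the input gradient is the 'same'
    convolution of the output gradient with the spatially flipped,
    in/out-transposed kernel.
    """

    def __init__(self, in_ch, out_ch, ksize=3, init="glorot", rng=None, dtype=DTYPE):
        super().__init__()
        if ksize not in (1, 3):
            raise ValueError("Conv2D supports kernel sizes 1 and 3")
        rng = rng or np.random.default_rng(0)
        self.ksize = ksize
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = ksize * ksize * in_ch
        fan_out = ksize * ksize * out_ch
        shape = (ksize, ksize, in_ch, out_ch)
        if init == "orthogonal":
            w = orthogonal(shape, rng, dtype=dtype)
        else:
            w = glorot_uniform(shape, fan_in, fan_out, rng, dtype=dtype)
        self.params = {"w": w, "b": np.zeros(out_ch, dtype=dtype)}
        self._xp = None

    @staticmethod
    def _conv(x, w):
        k = w.shape[0]
        if k == 1:
            return np.tensordot(x, w[0, 0], axes=([3], [0]))
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # B,H,W,C,k,k
        return np.tensordot(win, w, axes=([4, 5, 3], [0, 1, 2]))

    def forward(self, x, training=False):
        self._x = x
        return self._conv(x, self.params["w"]) + self.params["b"]

    def backward(self, dy):
        x, w, k = self._x, self.params["w"], self.ksize
        if k == 1:
            dw = np.tensordot(x, dy, axes=([0, 1, 2], [0, 1, 2]))[None, None]
        else:
            p = k // 2
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            win = sliding_window_view(xp, (k, k), axis=(1, 2))
            # contract over batch and space -> (C,k,k,O) -> (k,k,C,O)
            dw = np.tensordot(win, dy, axes=([0, 1, 2], [0, 1, 2]))
            dw = dw.transpose(1, 2, 0, 3)
        self.grads = {"w": dw.astype(w.dtype), "b": dy.sum(axis=(0, 1, 2))}
        wt = w[::-1, ::-1].transpose(0, 1, 3, 2)  # flip space, swap in/out
        return self._conv(dy, wt)


class Dense(Layer):
    def __init__(self, in_dim, out_dim, init="glorot", rng=None, dtype=DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if init == "orthogonal":
            w = orthogonal((in_dim, out_dim), rng, dtype=dtype)
        else:
            w = glorot_uniform((in_dim, out_dim), in_dim, out_dim, rng, dtype=dtype)
        self.params = {"w": w, "b": np.zeros(out_dim, dtype=dtype)}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"w": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["w"].T


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; ties share the gradient equally."""

    def forward(self, x, training=False):
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._xr, self._out = xr, out
        return out

    def backward(self, dy):
        mask = self._xr == self._out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxr = mask * (dy[:, :, None, :, None, :] / counts)
        b, hh, _, ww, _, c = dxr.shape
        return dxr.reshape(b, hh * 2, ww * 2, c).astype(dy.dtype)


class Upsample2D(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, training=False):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy):
        b, h, w, c = dy.shape
        return dy.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (batch, height, width).

    Keras-style defaults: momentum 0.99, eps 1e-3. Running statistics are
    updated only in training mode; frozen/eval passes use them unchanged.
    """

    def __init__(self, ch, momentum=0.99, eps=1e-3, dtype=DTYPE):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(ch, dtype=dtype),
            "beta": np.zeros(ch, dtype=dtype),
        }
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(x.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        g, xhat, inv = self.params["gamma"], self._xhat, self._inv
        self.grads = {
            "gamma": (dy * xhat).sum(axis=(0, 1, 2)),
            "beta": dy.sum(axis=(0, 1, 2)),
        }
        if not self._training:
            return (dy * g * inv).astype(dy.dtype)
        n = dy.shape[0] * dy.shape[1] * dy.shape[2]
        s1 = dy.sum(axis=(0, 1, 2)) / n
        s2 = (dy * xhat).sum(axis=(0, 1, 2)) / n
        return (g * inv * (dy - s1 - xhat * s2)).astype(dy.dtype)


class Dropout(Layer):
    """Inverted dropout; active only in training mode. Needs ``self.rng``."""

    def __init__(self, rate):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope=0.3):
        super().__init__()
        self.slope = slope

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy).astype(dy.dtype)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        # numerically stable logistic (no overflow for large |x|)
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return self._out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def sublayers(self):
        out = []
        for layer in self.layers:
            out.extend(layer.sublayers())
        return out


class UNet(Layer):
    """Encoder-decoder with skip connections for image-to-image regression.

    ``depth`` contraction levels of two 3x3 conv+ReLU layers and a 2x2
    max-pool, a bottleneck, and mirrored expansion levels that upsample,
    halve the channel count with a 3x3 conv, concatenate the skip and
    apply two further convs. A final 1x1 conv + ReLU yields one
    non-negative output channel (a valid density map).
    """

    def __init__(self, in_ch=1, depth=4, base_filters=32, rng=None, dtype=DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        f = [base_filters * 2 ** d for d in range(depth + 1)]
        mk = lambda ci, co: Conv2D(ci, co, 3, rng=rng, dtype=dtype)
        self.enc = []
        ci = in_ch
        for d in range(depth):
            self.enc.append(Sequential([mk(ci, f[d]), ReLU(), mk(f[d], f[d]), ReLU()]))
            ci = f[d]
        self.pools = [MaxPool2D() for _ in range(depth)]
        self.bottom = Sequential([mk(f[depth - 1], f[depth]), ReLU(),
                                  mk(f[depth], f[depth]), ReLU()])
        self.ups = [Upsample2D() for _ in range(depth)]
        self.upconvs = [mk(f[d + 1], f[d]) for d in range(depth)]
        self.dec = [Sequential([mk(2 * f[d], f[d]), ReLU(), mk(f[d], f[d]), ReLU()])
                    for d in range(depth)]
        self.final = Conv2D(f[0], 1, 1, rng=rng, dtype=dtype)
        # start the non-negative output in its active regime: a zero bias
        # lets MSE against sparse density targets kill every ReLU unit
        # before structure is learned
        self.final.params["b"][:] = 0.5
        self.outact = ReLU()

    def sublayers(self):
        out = []
        for blk in self.enc:
            out.extend(blk.sublayers())
        out.extend(self.pools)
        out.extend(self.bottom.sublayers())
        out.extend(self.ups)
        out.extend(self.upconvs)
        for blk in self.dec:
            out.extend(blk.sublayers())
        out.append(self.final)
        out.append(self.outact)
        return out

    def forward(self, x, training=False):
        skips = []
        for d in range(self.depth):
            x = self.enc[d].forward(x, training=training)
            skips.append(x)
            x = self.pools[d].forward(x, training=training)
        x = self.bottom.forward(x, training=training)
        for d in reversed(range(self.depth)):
            x = self.ups[d].forward(x, training=training)
            x = self.upconvs[d].forward(x, training=training)
            x = np.concatenate([skips[d], x], axis=-1)
            x = self.dec[d].forward(x, training=training)
        self._nskip = [s.shape[-1] for s in skips]
        x = self.final.forward(x, training=training)
        return self.outact.forward(x, training=training)

    def backward(self, dy):
        dy = self.outact.backward(dy)
        dy = self.final.backward(dy)
        dskips = [None] * self.depth
        for d in range(self.depth):
            dy = self.dec[d].backward(dy)
            c = self._nskip[d]
            dskips[d], dy = dy[..., :c], dy[..., c:]
            dy = self.upconvs[d].backward(dy)
            dy = self.ups[d].backward(dy)
        dy = self.bottom.backward(dy)
        for d in reversed(range(self.depth)):
            dy = self.pools[d].backward(dy)
            dy = dy + dskips[d]
            dy = self.enc[d].backward(dy)
        return dy


# ---------------------------------------------------------------------------
# parameter bookkeeping, optimizer, loss
# ---------------------------------------------------------------------------

def named_params(module: Layer, prefix=""):
    """Deterministic (name, layer, key) triples over every parameter."""
    out = []
    for i, layer in enumerate(module.sublayers()):
        for key in layer.params:
            out.append((f"{prefix}layer{i:03d}/{key}", layer, key))
    return out


def get_weights(module: Layer, prefix=""):
    state = {name: layer.params[key].copy()
             for name, layer, key in named_params(module, prefix)}
    for i, layer in enumerate(module.sublayers()):
        if isinstance(layer, BatchNorm2D):
            state[f"{prefix}layer{i:03d}/running_mean"] = layer.running_mean.copy()
            state[f"{prefix}layer{i:03d}/running_var"] = layer.running_var.copy()
    return state


def set_weights(module: Layer, state, prefix=""):
    for name, layer, key in named_params(module, prefix):
        if name not in state:
            raise ValueError(f"missing weight {name!r}")
        if state[name].shape != layer.params[key].shape:
            raise ValueError(
                f"shape mismatch for {name!r}: "
                f"{state[name].shape} vs {layer.params[key].shape}")
        layer.params[key] = state[name].copy()
    for i, layer in enumerate(module.sublayers()):
        if isinstance(layer, BatchNorm2D):
            rm = state.get(f"{prefix}layer{i:03d}/running_mean")
            rv = state.get(f"{prefix}layer{i:03d}/running_var")
            if rm is not None:
                layer.running_mean = rm.copy()
            if rv is not None:
                layer.running_var = rv.copy()


class Adam:
    """Adam with Keras defaults (beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, triples):
        """Update parameters in-place given (name, layer, key) triples."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for name, layer, key in triples:
            g = layer.grads[key]
            pid = id(layer.params[key])
            m, v = self.state.get(pid, (np.zeros_like(g), np.zeros_like(g)))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            p = layer.params[key]
            p -= (self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)).astype(p.dtype)
            self.state[pid] = (m, v)


def mse_loss(pred, target):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(pred.dtype)


def set_dropout_rng(module: Layer, rng):
    for layer in module.sublayers():
        if isinstance(layer, Dropout):
            layer.rng = rng


def reestimate_bn_stats(module: Layer, x, batch_size=16):
    """Recompute batch-norm running statistics with dropout disabled.

    Dropout upstream of a batch-norm layer inflates the activation
    variance seen during training, so running statistics accumulated
    there misrepresent the dropout-free evaluation regime and bias every
    prediction. After training we replace them with the plain average of
    batch statistics over ``x`` computed without dropout.
    """
    bns = [l for l in module.sublayers() if isinstance(l, BatchNorm2D)]
    if not bns:
        return
    drops = [l for l in module.sublayers() if isinstance(l, Dropout)]
    saved_rates = [d.rate for d in drops]
    for d in drops:
        d.rate = 0.0
    for bn in bns:
        bn.running_mean = np.zeros_like(bn.running_mean)
        bn.running_var = np.zeros_like(bn.running_var)
    try:
        n_batches = max(1, int(np.ceil(len(x) / batch_size)))
        for i in range(n_batches):
            # momentum i/(i+1) turns the EMA into a cumulative average
            for bn in bns:
                bn.momentum = i / (i + 1.0)
            module.forward(x[i * batch_size:(i + 1) * batch_size],
                           training=True)
    finally:
        for d, r in zip(drops, saved_rates):
            d.rate = r
        for bn in bns:
            bn.momentum = 0.99
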