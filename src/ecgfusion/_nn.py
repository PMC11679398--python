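"""Minimal numpy layer stack used by the fusion models.

Implements exactly the layer types the customized AlexNet needs — 2-D
convolution, batch normalization, max pooling, dense, dropout, flatten,
input rescaling and channel/feature concatenation — with explicit forward
and backward passes and an Adam optimizer.  Data layout is NHWC throughout
so layer output shapes read like the architecture table.

This is a small, transparent engine, not a general autodiff framework:
the model graph is restricted to a sequential chain, optionally preceded
by two parallel branches merged by a single concatenation (all the fusion
topologies used here).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Rescaling", "Conv2D", "BatchNorm", "MaxPool2D", "Flatten",
    "Dense", "Dropout", "Concatenate", "Sequential", "TwoBranchModel",
    "Adam", "softmax", "softmax_cross_entropy",
]


class Layer:
    """Base layer: named, with (possibly empty) parameter dicts.

    ``params`` holds trainable arrays, ``state`` holds non-trainable
    arrays (batch-norm running statistics).  ``grads`` mirrors ``params``
    after a backward pass.
    """

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def build(self, input_shape, rng):  # input_shape excludes batch dim
        raise NotImplementedError

    def forward(self, x, training: bool):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    @property
    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    @property
    def n_non_trainable(self) -> int:
        return int(sum(p.size for p in self.state.values()))


class Rescaling(Layer):
    """Multiply inputs by a fixed factor (1/255: 8-bit image -> [0,1])."""

    def __init__(self, scale=1.0 / 255.0, name="Rescaling"):
        super().__init__(name)
        self.scale = float(scale)

    def build(self, input_shape, rng):
        return input_shape

    def forward(self, x, training):
        return x * self.scale

    def backward(self, grad):
        return grad * self.scale


def _im2col(x, kh, kw, stride):
    """(N,H,W,C) -> (N,Ho,Wo,kh,kw,C) strided view (no copy)."""
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # v: (N, H-kh+1, W-kw+1, C, kh, kw)
    v = v[:, ::stride, ::stride]
    return np.ascontiguousarray(np.moveaxis(v, 3, 5))  # (N,Ho,Wo,kh,kw,C)


class Conv2D(Layer):
    """2-D convolution (cross-correlation), VALID or SAME padding, + ReLU option."""

    def __init__(self, filters, kernel_size, stride=1, padding="same",
                 activation="relu", name="Conv"):
        super().__init__(name)
        self.filters = int(filters)
        self.kh = self.kw = int(kernel_size)
        self.stride = int(stride)
        assert padding in ("same", "valid")
        self.padding = padding
        self.activation = activation

    def build(self, input_shape, rng):
        h, w, cin = input_shape
        self.cin = cin
        fan_in = self.kh * self.kw * cin
        # He-uniform, the common default for ReLU conv stacks
        limit = np.sqrt(6.0 / fan_in)
        self.params["W"] = rng.uniform(
            -limit, limit, size=(self.kh, self.kw, cin, self.filters)
        ).astype(np.float32)
        self.params["b"] = np.zeros(self.filters, dtype=np.float32)
        if self.padding == "same":
            ho = -(-h // self.stride)
            wo = -(-w // self.stride)
            self.pad_h = max((ho - 1) * self.stride + self.kh - h, 0)
            self.pad_w = max((wo - 1) * self.stride + self.kw - w, 0)
        else:
            ho = (h - self.kh) // self.stride + 1
            wo = (w - self.kw) // self.stride + 1
            self.pad_h = self.pad_w = 0
        self.out_shape = (ho, wo, self.filters)
        return self.out_shape

    def _pad(self, x):
        if self.pad_h == 0 and self.pad_w == 0:
            return x
        pt, pb = self.pad_h // 2, self.pad_h - self.pad_h // 2
        pl, pr = self.pad_w // 2, self.pad_w - self.pad_w // 2
        return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))

    def forward(self, x, training):
        xp = self._pad(x.astype(np.float32, copy=False))
        cols = _im2col(xp, self.kh, self.kw, self.stride)
        n, ho, wo = cols.shape[:3]
        cols2 = cols.reshape(n * ho * wo, -1)
        Wm = self.params["W"].reshape(-1, self.filters)
        z = (cols2 @ Wm).reshape(n, ho, wo, self.filters) + self.params["b"]
        self._cache = (x.shape, cols2, (n, ho, wo))
        if self.activation == "relu":
            self._relu_mask = z > 0
            z = np.where(self._relu_mask, z, 0.0)
        return z

    def backward(self, grad):
        x_shape, cols2, (n, ho, wo) = self._cache
        if self.activation == "relu":
            grad = grad * self._relu_mask
        g2 = grad.reshape(n * ho * wo, self.filters)
        self.grads["W"] = (cols2.T @ g2).reshape(self.params["W"].shape)
        self.grads["b"] = g2.sum(axis=0)
        # col2im: scatter-add the column gradients back onto the padded input
        Wm = self.params["W"].reshape(-1, self.filters)
        dcols = (g2 @ Wm.T).reshape(n, ho, wo, self.kh, self.kw, self.cin)
        hp = x_shape[1] + self.pad_h
        wp = x_shape[2] + self.pad_w
        dxp = np.zeros((n, hp, wp, self.cin), dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + ho * self.stride:self.stride,
                    j:j + wo * self.stride:self.stride] += dcols[:, :, :, i, j]
        pt = self.pad_h // 2
        pl = self.pad_w // 2
        return dxp[:, pt:pt + x_shape[1], pl:pl + x_shape[2]]


class BatchNorm(Layer):
    """Per-channel batch normalization (4 params/channel, 2 trainable)."""

    # momentum 0.6: running statistics track within ~10 batches, so
    # validation-loss monitoring is meaningful even when an epoch has few
    # batches; with many batches per epoch the choice is uncritical
    def __init__(self, momentum=0.6, eps=1e-3, name="BN"):
        super().__init__(name)
        self.momentum = momentum
        self.eps = eps

    def build(self, input_shape, rng):
        c = input_shape[-1]
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.state["moving_mean"] = np.zeros(c, dtype=np.float32)
        self.state["moving_var"] = np.ones(c, dtype=np.float32)
        self._axes = tuple(range(len(input_shape)))  # reduce all but channel
        return input_shape

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.state["moving_mean"] = (m * self.state["moving_mean"]
                                         + (1 - m) * mu).astype(np.float32)
            self.state["moving_var"] = (m * self.state["moving_var"]
                                        + (1 - m) * var).astype(np.float32)
        else:
            mu = self.state["moving_mean"]
            var = self.state["moving_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, axes, x.shape, training)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad):
        xhat, inv, axes, shape, training = self._cache
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        if not training:
            # inference: running statistics are constants
            return (grad * self.params["gamma"] * inv).astype(
                np.float32, copy=False)
        m = np.prod([shape[a] for a in axes])
        g = grad * self.params["gamma"]
        # standard batch-norm backward (through batch statistics)
        dx = (inv / m) * (m * g - g.sum(axis=axes)
                          - xhat * (g * xhat).sum(axis=axes))
        return dx.astype(np.float32, copy=False)


class MaxPool2D(Layer):
    def __init__(self, pool_size=3, stride=2, name="Pool"):
        super().__init__(name)
        self.k = int(pool_size)
        self.stride = int(stride)

    def build(self, input_shape, rng):
        h, w, c = input_shape
        ho = (h - self.k) // self.stride + 1
        wo = (w - self.k) // self.stride + 1
        if ho < 1 or wo < 1:
            raise ValueError(
                f"{self.name}: spatial size {h}x{w} too small for "
                f"{self.k}x{self.k}/{self.stride} valid pooling")
        self.out_shape = (ho, wo, c)
        return self.out_shape

    def forward(self, x, training):
        cols = _im2col(x, self.k, self.k, self.stride)  # (N,Ho,Wo,k,k,C)
        n, ho, wo = cols.shape[:3]
        c = cols.shape[-1]
        flat = cols.reshape(n, ho, wo, self.k * self.k, c)
        self._arg = flat.argmax(axis=3)  # (N,Ho,Wo,C)
        self._x_shape = x.shape
        return flat.max(axis=3)

    def backward(self, grad):
        n, h, w, c = self._x_shape
        ho, wo = grad.shape[1:3]
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        ki = self._arg // self.k
        kj = self._arg % self.k
        ni, hi, wi, ci = np.indices(grad.shape, sparse=False)
        rows = hi * self.stride + ki
        colsj = wi * self.stride + kj
        np.add.at(dx, (ni, rows, colsj, ci), grad)
        return dx


class Flatten(Layer):
    def __init__(self, name="Flatten"):
        super().__init__(name)

    def build(self, input_shape, rng):
        self._in = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, training):
        self._n = x.shape[0]
        return x.reshape(self._n, -1)

    def backward(self, grad):
        return grad.reshape((self._n,) + self._in)


class Dense(Layer):
    def __init__(self, units, activation=None, name="FC"):
        super().__init__(name)
        self.units = int(units)
        self.activation = activation  # None | "relu" (softmax applied in loss)

    def build(self, input_shape, rng):
        (d,) = input_shape
        limit = np.sqrt(6.0 / d)
        self.params["W"] = rng.uniform(
            -limit, limit, size=(d, self.units)).astype(np.float32)
        self.params["b"] = np.zeros(self.units, dtype=np.float32)
        return (self.units,)

    def forward(self, x, training):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            z = np.where(self._mask, z, 0.0)
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate=0.5, name="Dr"):
        super().__init__(name)
        self.rate = float(rate)
        self.rng = np.random.default_rng(0)

    def reseed(self, rng):
        self.rng = rng

    def build(self, input_shape, rng):
        return input_shape

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Concatenate(Layer):
    """Marks the merge point; concatenation itself happens in TwoBranchModel."""

    def __init__(self, axis=-1, name="Concat"):
        super().__init__(name)
        self.axis = axis

    def build(self, input_shapes, rng):
        a, b = input_shapes
        ax = self.axis if self.axis >= 0 else len(a) + self.axis
        out = list(a)
        out[ax] = a[ax] + b[ax]
        self._split = a[ax]
        return tuple(out)

    def forward(self, xs, training):
        return np.concatenate(xs, axis=self.axis)

    def backward(self, grad):
        return np.split(grad, [self._split], axis=self.axis)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, y_onehot):
    """Returns (mean loss, gradient wrt logits)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.sum(y_onehot * np.log(p + eps)) / n
    return loss, (p - y_onehot) / n


class Sequential:
    """Plain layer chain.  ``capture`` in forward/backward supports Grad-CAM."""

    def __init__(self, layers, input_shape, rng):
        self.layers = list(layers)
        shape = tuple(input_shape)
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.reseed(np.random.default_rng(rng.integers(2**31)))
            shape = layer.build(shape, rng)
        self.output_shape = shape

    # -- inference / training plumbing ------------------------------------
    def forward(self, x, training=False, capture=None):
        captured = {}
        for layer in self.layers:
            x = layer.forward(x, training)
            if capture and layer.name in capture:
                captured[layer.name] = x
        self._captured = captured
        return x

    def backward(self, grad, capture=None):
        captured = {}
        for layer in reversed(self.layers):
            if capture and layer.name in capture:
                captured[layer.name] = grad
            grad = layer.backward(grad)
        self._grad_captured = captured
        return grad

    def iter_layers(self):
        yield from self.layers


class TwoBranchModel:
    """Two identical-topology branches merged by concatenation, then a tail.

    The input carries both modalities as channels; channel 0 feeds branch A
    (scalograms) and channel 1 feeds branch B (phasograms).
    """

    def __init__(self, branch_a, branch_b, concat: Concatenate, tail_layers,
                 input_shape, rng):
        self.branch_a = branch_a
        self.branch_b = branch_b
        self.concat = concat
        out = concat.build((branch_a.output_shape, branch_b.output_shape), rng)
        shape = out
        self.tail = Sequential.__new__(Sequential)
        self.tail.layers = list(tail_layers)
        for layer in self.tail.layers:
            if isinstance(layer, Dropout):
                layer.reseed(np.random.default_rng(rng.integers(2**31)))
            shape = layer.build(shape, rng)
        self.tail.output_shape = shape
        self.output_shape = shape

    def forward(self, x, training=False, capture=None):
        xa = x[..., 0:1]
        xb = x[..., 1:2]
        za = self.branch_a.forward(xa, training, capture=capture)
        zb = self.branch_b.forward(xb, training, capture=capture)
        z = self.concat.forward([za, zb], training)
        out = self.tail.forward(z, training, capture=capture)
        self._captured = {**self.branch_a._captured, **self.branch_b._captured,
                          **self.tail._captured}
        return out

    def backward(self, grad, capture=None):
        grad = self.tail.backward(grad, capture=capture)
        ga, gb = self.concat.backward(grad)
        da = self.branch_a.backward(ga, capture=capture)
        db = self.branch_b.backward(gb, capture=capture)
        self._grad_captured = {**self.branch_a._grad_captured,
                               **self.branch_b._grad_captured,
                               **self.tail._grad_captured}
        return np.concatenate([da, db], axis=-1)

    def iter_layers(self):
        yield from self.branch_a.layers
        yield from self.branch_b.layers
        yield self.concat
        yield from self.tail.layers


class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, model, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model = model
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for li, layer in enumerate(model.iter_layers()):
            for k, p in layer.params.items():
                self.m[(li, k)] = np.zeros_like(p)
                self.v[(li, k)] = np.zeros_like(p)

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for li, layer in enumerate(self.model.iter_layers()):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m = self.m[(li, k)]
                v = self.v[(li, k)]
                m += (1 - self.b1) * (g - m)
                v += (1 - self.b2) * (g * g - v)
                p -= lr_t * m / (np.sqrt(v) + self.eps)
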