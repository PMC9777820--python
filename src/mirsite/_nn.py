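"""A small CPU neural-network engine for 20x50 binding-matrix scorers.

Implements exactly the layer set the scorers need — 2-D convolution
(im2col), batch normalization, leaky ReLU, max pooling, dropout, dense
layers, residual blocks and global average pooling — together with
reverse-mode gradients, an Adam optimizer and a binary cross-entropy
loss that accepts soft targets in [0, 1].  Everything is float32 and
deterministic given the RNG passed in at construction.

This module is internal; the public model surface lives in
:mod:`mirsite.models`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base layer: forward/backward plus named parameter/gradient dicts."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def children(self) -> list["Layer"]:
        return []

    def state(self) -> dict:
        """Extra non-trainable state to checkpoint (e.g. BN running stats)."""
        return {}


def _he_uniform(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Conv2D(Layer):
    """Same-padded (k odd) 2-D convolution, stride 1, via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.params = {
            "W": _he_uniform(rng, cin * k * k, (cout, cin * k * k)),
            "b": np.zeros(cout, dtype=F32),
        }

    def forward(self, x, train):
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n,c,h,w,k,k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        out = cols @ self.params["W"].T + self.params["b"]
        self._cache = (x.shape, cols)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, g):
        (n, c, h, w), cols = self._cache
        k, p = self.k, self.k // 2
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.grads = {"W": gm.T @ cols, "b": gm.sum(axis=0)}
        gcols = (gm @ self.params["W"]).reshape(n, h, w, c, k, k)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + h, j : j + w] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        self._cache = None
        return gxp[:, :, p : p + h, p : p + w]


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(c, dtype=F32), "beta": np.zeros(c, dtype=F32)}
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def _axes_shape(self, x):
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        return (0,), (1, -1)

    def forward(self, x, train):
        axes, shape = self._axes_shape(x)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(shape)) / std.reshape(shape)
        if train:
            self._cache = (xhat, std, axes, shape, x.shape)
        return self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(
            shape
        )

    def backward(self, g):
        xhat, std, axes, shape, xshape = self._cache
        n_eff = np.prod([xshape[a] for a in axes])
        self.grads = {
            "gamma": (g * xhat).sum(axis=axes),
            "beta": g.sum(axis=axes),
        }
        gxhat = g * self.params["gamma"].reshape(shape)
        gx = (
            gxhat
            - gxhat.mean(axis=axes, keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
        ) / std.reshape(shape)
        self._cache = None
        return gx.astype(F32)

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train):
        mask = x >= 0
        if train:
            self._mask = mask
        else:
            self._mask = mask  # also needed when backward follows an eval pass
        return np.where(mask, x, self.alpha * x)

    def backward(self, g):
        out = np.where(self._mask, g, self.alpha * g)
        self._mask = None
        return out


class MaxPool2D(Layer):
    """Floor-mode max pooling; trailing rows/cols that do not fill a
    window are dropped (and receive zero gradient)."""

    def __init__(self, ph: int, pw: int):
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x, train):
        n, c, h, w = x.shape
        ph, pw = self.ph, self.pw
        h2, w2 = h // ph, w // pw
        xc = x[:, :, : h2 * ph, : w2 * pw]
        windows = xc.reshape(n, c, h2, ph, w2, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2, w2, ph * pw
        )
        arg = windows.argmax(axis=-1)
        self._cache = (x.shape, arg)
        return np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    def backward(self, g):
        (n, c, h, w), arg = self._cache
        ph, pw = self.ph, self.pw
        h2, w2 = h // ph, w // pw
        gwin = np.zeros((n, c, h2, w2, ph * pw), dtype=F32)
        np.put_along_axis(gwin, arg[..., None], g[..., None].astype(F32), axis=-1)
        gx = np.zeros((n, c, h, w), dtype=F32)
        gx[:, :, : h2 * ph, : w2 * pw] = (
            gwin.reshape(n, c, h2, w2, ph, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
                n, c, h2 * ph, w2 * pw
            )
        )
        self._cache = None
        return gx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None  # set by Network

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(F32) / F32(1.0 - self.p)
        self._mask = keep
        return x * keep

    def backward(self, g):
        if self._mask is None:
            return g
        out = g * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        n, c, h, w = self._shape
        return (np.broadcast_to(g[:, :, None, None], self._shape) / F32(h * w)).astype(
            F32
        )


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _he_uniform(rng, nin, (nin, nout)),
            "b": np.zeros(nout, dtype=F32),
        }

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads = {"W": self._x.T @ g, "b": g.sum(axis=0)}
        out = g @ self.params["W"].T
        self._x = None
        return out


class Residual(Layer):
    """Two-convolution residual block with an optional 1x1 projection skip."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3, alpha: float = 0.1):
        super().__init__()
        self.body = [
            Conv2D(cin, cout, k, rng),
            BatchNorm(cout),
            LeakyReLU(alpha),
            Conv2D(cout, cout, k, rng),
            BatchNorm(cout),
        ]
        self.proj = [Conv2D(cin, cout, 1, rng)] if cin != cout else []
        self.act = LeakyReLU(alpha)

    def children(self):
        return self.body + self.proj + [self.act]

    def forward(self, x, train):
        h = x
        for layer in self.body:
            h = layer.forward(h, train)
        s = x
        for layer in self.proj:
            s = layer.forward(s, train)
        return self.act.forward(h + s, train)

    def backward(self, g):
        g = self.act.backward(g)
        gh = g
        for layer in reversed(self.body):
            gh = layer.backward(gh)
        gs = g
        for layer in reversed(self.proj):
            gs = layer.backward(gs)
        return gh + gs


class Network:
    """A sequential stack of layers with shared RNG for dropout masks."""

    def __init__(self, layers: list[Layer], rng: np.random.Generator):
        self.layers = layers
        self.rng = rng
        for layer in self._flat():
            if isinstance(layer, Dropout):
                layer.rng = rng

    def _flat(self) -> list[Layer]:
        out: list[Layer] = []

        def walk(layers):
            for layer in layers:
                out.append(layer)
                walk(layer.children())

        walk(self.layers)
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameter_items(self) -> list[tuple[str, Layer, str]]:
        items = []
        for i, layer in enumerate(self._flat()):
            for name in layer.params:
                items.append((f"{i}.{name}", layer, name))
        return items

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for _, layer, name in self.parameter_items())

    def snapshot(self) -> dict[str, np.ndarray]:
        """Copy of all parameters and layer state (for best-epoch restore)."""
        out = {}
        for key, layer, name in self.parameter_items():
            out[key] = layer.params[name].copy()
        for i, layer in enumerate(self._flat()):
            for sname, arr in layer.state().items():
                out[f"{i}.state.{sname}"] = arr.copy()
        return out

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.parameter_items():
            layer.params[name] = snap[key].copy()
        for i, layer in enumerate(self._flat()):
            for sname in layer.state():
                setattr(layer, sname, snap[f"{i}.state.{sname}"].copy())


class Adam:
    """Adaptive-moment gradient optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, net: Network, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for key, layer, name in self.net.parameter_items():
            g = layer.grads.get(name)
            if g is None:
                continue
            g = g.astype(F32)
            m = self.m.get(key)
            if m is None:
                m = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            v = self.v[key]
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.m[key], self.v[key] = m, v
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            layer.params[name] = (
                layer.params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(F32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy against (possibly soft) targets.

    Returns (loss, dloss/dz) with the gradient already divided by the
    batch size.  loss = mean(softplus(z) - t*z), grad = (sigmoid(z)-t)/n.
    """
    z = z.astype(np.float64)
    t = t.astype(np.float64)
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    loss = float(np.mean(softplus - t * z))
    grad = ((sigmoid(z) - t) / z.shape[0]).astype(F32)
    return loss, grad
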