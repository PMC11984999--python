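"""A small CPU neural-network engine on NumPy arrays.

Layers cache what their backward pass needs on forward; parameters and
gradients are plain float32 ndarrays exposed through flat name->array dicts,
so model state is trivially serializable and federated parameter averaging is
a dict comprehension. Convolutions run as im2col + BLAS matmul, which is fast
enough for the desk-scale images (32-512 px) this toolkit trains on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: optional parameters plus cached-forward/backward."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution, NCHW, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin * k * k)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.cin, self.cout = cin, cout
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = cols @ self.W.T + self.b
        self._cols = cols
        self._xshape = (n, c, h, w)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gout):
        n, c, h, w = self._xshape
        g2 = np.ascontiguousarray(gout.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.dW[...] = g2.T @ self._cols
        self.db[...] = g2.sum(axis=0)
        dcols = (g2 @ self.W).reshape(n, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gout):
        return np.where(self._mask, gout, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling; input H, W must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, gout):
        n, c, h, w = self._shape
        gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gflat, self._arg[..., None], gout[..., None], axis=-1)
        return (
            gflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gout):
        n, c, h, w = gout.shape
        return gout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None] / (h * w), self._shape).astype(
            np.float32
        )


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.W = (rng.standard_normal((cout, cin)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gout):
        self.dW[...] = gout.T @ self._x
        self.db[...] = gout.sum(axis=0)
        return gout @ self.W


class Module:
    """A named collection of layers with a flat state dict."""

    def __init__(self):
        self._layers: dict[str, Layer] = {}

    def add(self, name: str, layer: Layer) -> Layer:
        self._layers[name] = layer
        return layer

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._layers.items():
            for pname, arr in layer.params().items():
                out[f"{lname}.{pname}"] = arr
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._layers.items():
            for pname, arr in layer.grads().items():
                out[f"{lname}.{pname}"] = arr
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise ValueError(f"state dict does not match architecture: {sorted(missing)}")
        for k, v in state.items():
            if params[k].shape != v.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {params[k].shape} vs {v.shape}"
                )
            params[k][...] = v

    def n_parameters(self) -> int:
        return sum(int(p.size) for p in self.parameters().values())

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.ascontiguousarray(x, dtype=np.float32))


class Adam:
    """Adam with in-place parameter updates (state keyed by parameter name)."""

    def __init__(self, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            if k not in self.m:
                self.m[k] = np.zeros_like(p)
                self.v[k] = np.zeros_like(p)
            m, v = self.m[k], self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    dlogits = p.astype(np.float32)
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=z.dtype if np.issubdtype(z.dtype, np.floating) else np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_dice_loss(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy plus soft-Dice loss for segmentation logits.

    ``logits`` and ``target`` are (N, 1, H, W); returns the scalar loss and
    its gradient with respect to the logits.
    """
    z = np.asarray(logits)
    dtype = z.dtype if np.issubdtype(z.dtype, np.floating) else np.float64
    t = np.asarray(target, dtype=dtype)
    n = z.shape[0]
    npix = z[0].size

    bce = float((np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean())
    p = sigmoid(z)
    dbce = (p - t) / (n * npix)

    eps = 1.0
    axes = (1, 2, 3)
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2.0 * inter + eps) / (denom + eps)
    dice_loss = float(1.0 - dice.mean())
    # d(dice_i)/dp = (2 t (denom+eps) - (2 inter+eps)) / (denom+eps)^2
    dd = (2.0 * t * (denom + eps)[:, None, None, None] - (2.0 * inter + eps)[:, None, None, None]) / (
        (denom + eps) ** 2
    )[:, None, None, None]
    ddice = -dd / n
    # dbce is already wrt the logits; the dice term chains through the sigmoid
    dlogits = (dbce + ddice * p * (1.0 - p)).astype(dtype)
    return bce + dice_loss, dlogits


def epoch_rng(base_seed: int, epoch_index: int) -> np.random.Generator:
    """The shuffle stream for one global epoch.

    Keyed by (seed, epoch index) so a federated client training local epochs
    e..e+E-1 of its schedule draws exactly the same shuffles as a centralized
    loop at the same global epoch indices.
    """
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), int(epoch_index)]))
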