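"""A small numpy engine for 1D convolutional classifiers.

Implements exactly the layer inventory the apnea classifier needs —
1D convolution ('same' padding, stride 1), batch normalization, ReLU,
max pooling (pool 2, stride 2), dropout, flatten, fully connected layers
and a softmax/cross-entropy head — together with He-normal initialization
and the Adam optimizer, all with explicit forward/backward passes.

Array convention: 3-D activations are (batch, length, channels); dense
activations are (batch, features).  Training-time stochasticity (dropout)
draws from a generator passed to ``forward``, so runs are reproducible
bit-for-bit given the seeds.
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

__all__ = [
    "Conv1D", "BatchNorm", "ReLU", "MaxPool1D", "Dropout", "Flatten",
    "Dense", "Network", "Adam", "softmax", "softmax_cross_entropy",
]


class Layer:
    """Base layer: parameters, gradients and persistent (non-trained) state."""

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def state(self) -> dict:
        """Persistent non-trainable arrays (e.g. BN moving statistics)."""
        return {}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, fan_in: int, shape, dtype) -> np.ndarray:
    """He-normal initialization: N(0, sqrt(2/fan_in)), fan-in of the input."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' padding (output length == input).

    Implemented as a loop over the kernel taps, each tap a strided BLAS
    matmul against a shifted view of the padded input; this avoids the
    k-fold im2col blow-up and keeps the working set cache-resident.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = kernel_size * in_channels
        self.W = he_normal(rng, fan_in,
                           (kernel_size, in_channels, out_channels), dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        # 'same' padding for even kernels: (k-1)//2 left, k//2 right
        self._pad = ((kernel_size - 1) // 2, kernel_size // 2)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        pl, pr = self._pad
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        out = np.empty((B, L, self.out_channels), dtype=x.dtype)
        out[...] = self.b
        for k0 in range(self.kernel_size):
            out += xp[:, k0:k0 + L, :] @ self.W[k0]
        self._cache = (xp, L)
        return out

    def backward(self, grad):
        xp, L = self._cache
        self.db[...] = grad.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for k0 in range(self.kernel_size):
            xs = xp[:, k0:k0 + L, :]
            self.dW[k0] = np.matmul(xs.transpose(0, 2, 1), grad).sum(axis=0)
            dxp[:, k0:k0 + L, :] += grad @ self.W[k0].T
        pl, _ = self._pad
        return dxp[:, pl:pl + L, :]


class BatchNorm(Layer):
    """Batch normalization over batch (and length, for 3-D inputs).

    Keras-era defaults: momentum 0.99 on the moving statistics, eps 1e-3.
    Inference normalizes with the moving mean/variance, so a trained model
    is deterministic at test time.
    """

    def __init__(self, channels: int, momentum: float = 0.99,
                 eps: float = 1e-3, dtype=np.float32):
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.moving_mean = np.zeros(channels, dtype=dtype)
        self.moving_var = np.ones(channels, dtype=dtype)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"moving_mean": self.moving_mean,
                "moving_var": self.moving_var}

    def _axes(self, x):
        return tuple(range(x.ndim - 1))

    def forward(self, x, training=False, rng=None):
        axes = self._axes(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean[...] = m * self.moving_mean + (1 - m) * mean
            self.moving_var[...] = m * self.moving_var + (1 - m) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv, axes,
                           int(np.prod([x.shape[a] for a in axes])))
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, inv, axes, n = self._cache
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        g = grad * self.gamma
        return inv / n * (n * g - g.sum(axis=axes)
                          - xhat * (g * xhat).sum(axis=axes))


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Max pooling with pool size 2, stride 2; odd trailing sample dropped."""

    def __init__(self, pool: int = 2, stride: int = 2):
        if pool != stride:
            raise ValueError("only pool == stride is supported")
        self.pool = pool

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        Lo = L // self.pool
        xr = x[:, :Lo * self.pool, :].reshape(B, Lo, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._shape = (B, L, C)
        return np.take_along_axis(xr, self._argmax[:, :, None, :],
                                  axis=2)[:, :, 0, :]

    def backward(self, grad):
        B, L, C = self._shape
        Lo = grad.shape[1]
        dxr = np.zeros((B, Lo, self.pool, C), dtype=grad.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, None, :],
                          grad[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C), dtype=grad.dtype)
        dx[:, :Lo * self.pool, :] = dxr.reshape(B, Lo * self.pool, C)
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a Generator")
        keep = 1.0 - self.rate
        u = rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.W = he_normal(rng, in_features, (in_features, out_features),
                           dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Network:
    """A feed-forward stack of layers ending in class logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference-mode class probabilities (deterministic)."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size],
                                            training=False)))
        return np.concatenate(out, axis=0)

    def train_step(self, x: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator) -> tuple[float, float]:
        """One forward/backward pass; returns (loss, accuracy) on the batch."""
        logits = self.forward(x, training=True, rng=rng)
        loss, grad = softmax_cross_entropy(logits, y)
        self.backward(grad)
        acc = float((logits.argmax(axis=1) == y).mean())
        return loss, acc

    # -- parameter bookkeeping ---------------------------------------------

    def named_params(self) -> Iterator[tuple[str, Layer, str]]:
        for i, layer in enumerate(self.layers):
            for name in layer.params():
                yield f"layer{i:02d}.{name}", layer, name

    def n_parameters(self, trainable_only: bool = False) -> int:
        total = 0
        for layer in self.layers:
            total += sum(p.size for p in layer.params().values())
            if not trainable_only:
                total += sum(s.size for s in layer.state().values())
        return total

    def state_dict(self) -> dict:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in {**layer.params(), **layer.state()}.items():
                out[f"layer{i:02d}.{name}"] = arr.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            both = {**layer.params(), **layer.state()}
            for name, arr in both.items():
                key = f"layer{i:02d}.{name}"
                if key not in state:
                    raise KeyError(f"missing parameter {key}")
                if state[key].shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: checkpoint "
                        f"{state[key].shape} vs model {arr.shape}")
                arr[...] = state[key]


class Adam:
    """Adam optimizer (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(layer.params()[n])
                  for k, layer, n in net.named_params()}
        self.v = {k: np.zeros_like(layer.params()[n])
                  for k, layer, n in net.named_params()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for key, layer, name in self.net.named_params():
            g = layer.grads()[name]
            m = self.m[key]
            v = self.v[key]
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            layer.params()[name][...] -= (
                self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps))
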