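"""Minimal feed-forward neural-network core: numpy layers with manual backprop.

Supports exactly what the pathway-masked VAE and the survival network need:
dense layers with optional fixed binary sparsity masks, batch normalization,
dropout, elementwise activations, and an Adam optimizer.  Layers cache their
forward inputs, so ``backward`` must be called on the same topology in reverse
order after each forward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "BatchNorm1d",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Dropout",
    "Sequential",
    "Adam",
    "add_l2_gradients",
    "l2_penalty",
]


class Param:
    """A learnable array with an accumulated gradient.

    ``regularized`` marks parameters included in L2 penalties (weights yes,
    biases and batchnorm scale/shift no).
    """

    __slots__ = ("value", "grad", "regularized", "name")

    def __init__(self, value: np.ndarray, regularized: bool = False, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.regularized = regularized
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, training=False):
        return self.forward(x, training=training)


class Dense(Layer):
    """Affine map ``y = x W + b`` with an optional fixed binary mask on W.

    Masked positions are zeroed at initialization and their gradients are
    zeroed on every backward pass, so they remain exactly 0 through training.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        bias: bool = True,
        mask: np.ndarray | None = None,
        name: str = "dense",
    ):
        bound = 1.0 / np.sqrt(n_in)
        W = rng.uniform(-bound, bound, size=(n_in, n_out))
        if mask is not None:
            mask = np.asarray(mask, dtype=np.float64)
            if mask.shape != (n_in, n_out):
                raise ValueError(
                    f"mask shape {mask.shape} != weight shape {(n_in, n_out)}"
                )
            W = W * mask
        self.mask = mask
        self.W = Param(W, regularized=True, name=f"{name}.W")
        self.b = Param(np.zeros(n_out), name=f"{name}.b") if bias else None
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W] if self.b is None else [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dout):
        gW = self._x.T @ dout
        if self.mask is not None:
            gW *= self.mask
        self.W.grad += gW
        if self.b is not None:
            self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class BatchNorm1d(Layer):
    """Per-feature batch normalization with running statistics for eval mode."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(n), name=f"{name}.gamma")
        self.beta = Param(np.zeros(n), name=f"{name}.beta")
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            m = x.mean(axis=0)
            v = x.var(axis=0)
            n = x.shape[0]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m
            unbiased = v * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            invstd = 1.0 / np.sqrt(v + self.eps)
            xhat = (x - m) * invstd
            self._cache = (xhat, invstd)
        else:
            invstd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * invstd
            self._cache = None
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        if self._cache is None:
            # eval mode: plain affine map
            return dout * self.gamma.value / np.sqrt(self.running_var + self.eps)
        xhat, invstd = self._cache
        n = dout.shape[0]
        self.gamma.grad += (dout * xhat).sum(axis=0)
        self.beta.grad += dout.sum(axis=0)
        dxhat = dout * self.gamma.value
        dx = (invstd / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        return dx

    def folded(self) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode affine equivalent: returns (scale, shift) with y = scale*x + shift."""
        scale = self.gamma.value / np.sqrt(self.running_var + self.eps)
        shift = self.beta.value - self.running_mean * scale
        return scale, shift


class ReLU(Layer):
    kind = "relu"

    def forward(self, x, training=False):
        self._x = x
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * (self._x > 0)


class Tanh(Layer):
    kind = "tanh"

    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sigmoid(Layer):
    kind = "sigmoid"

    def forward(self, x, training=False):
        self._y = sigmoid(x)
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Needs an rng set per fit."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training")
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def l2_penalty(params: list[Param], lam: float) -> float:
    """lam * sum of squared entries over regularized parameters."""
    if lam == 0.0:
        return 0.0
    return lam * float(sum(np.sum(p.value**2) for p in params if p.regularized))


def add_l2_gradients(params: list[Param], lam: float) -> None:
    if lam == 0.0:
        return
    for p in params:
        if p.regularized:
            p.grad += 2.0 * lam * p.value


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)
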