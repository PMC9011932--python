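"""Minimal NumPy neural-network core: layers with explicit backprop and Adam.

All layers operate on arrays whose *last* axis is the feature axis; any
leading axes (batch, node) are treated as independent samples. Gradients are
accumulated into ``Param.grad`` by ``backward`` calls and consumed by
:class:`Adam`. Computation is float32 end to end; repeated runs with the same
seed on the same machine are bit-identical because every stochastic choice
flows from an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32
_BN_EPS = 1e-5


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(DTYPE)


class Dense:
    """Affine map on the last axis: ``y = x @ W + b``."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, name: str = "dense") -> None:
        self.W = Param(glorot(rng, in_dim, out_dim), f"{name}.W")
        self.b = Param(np.zeros(out_dim), f"{name}.b") if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        flat_x = x.reshape(-1, x.shape[-1])
        flat_g = gy.reshape(-1, gy.shape[-1])
        self.W.grad += flat_x.T @ flat_g
        if self.b is not None:
            self.b.grad += flat_g.sum(axis=0)
        return gy @ self.W.value.T


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0)


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._keep: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._keep = None
            return x
        keep = (rng.random(x.shape) >= self.rate).astype(DTYPE)
        self._keep = keep / DTYPE(1.0 - self.rate)
        return x * self._keep

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._keep is None:
            return gy
        return gy * self._keep


class MaskedBatchNorm:
    """Per-feature batch normalization restricted to masked-in positions.

    Statistics are computed over every axis except the last, counting only
    positions where ``mask`` is 1, so zero-padded graph nodes never leak into
    the estimates. Inference uses exponential running estimates.
    """

    def __init__(self, n_features: int, momentum: float = 0.9,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(n_features), f"{name}.gamma")
        self.beta = Param(np.zeros(n_features), f"{name}.beta")
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum = momentum
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, mask: np.ndarray,
                training: bool) -> np.ndarray:
        m = mask.astype(DTYPE)[..., None]
        if training:
            count = m.sum()
            axes = tuple(range(x.ndim - 1))
            mean = (x * m).sum(axis=axes) / count
            var = (((x - mean) ** 2) * m).sum(axis=axes) / count
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std, m, mean)
        return (self.gamma.value * xhat + self.beta.value).astype(DTYPE, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, m, _ = self._cache
        gy = gy * m  # padded positions carry no gradient
        count = m.sum()
        axes = tuple(range(gy.ndim - 1))
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g_xhat = gy * self.gamma.value
        sum_g = g_xhat.sum(axis=axes)
        sum_gx = (g_xhat * xhat).sum(axis=axes)
        gx = inv_std * (g_xhat - (sum_g + xhat * sum_gx) * (m / count))
        return gx.astype(DTYPE, copy=False)


class MaskedMaxPool:
    """Global max over the node axis (-2), restricted to masked-in nodes."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        if not np.any(mask):
            raise ValueError("graph_pool requires at least one masked-in node")
        neg = np.where(mask[..., None].astype(bool), x, -np.inf)
        idx = np.argmax(neg, axis=-2)
        out = np.take_along_axis(x, idx[..., None, :], axis=-2).squeeze(-2)
        self._cache = (x.shape, idx)
        return out.astype(DTYPE, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        shape, idx = self._cache
        gx = np.zeros(shape, dtype=DTYPE)
        np.put_along_axis(gx, idx[..., None, :], gy[..., None, :], axis=-2)
        return gx


class Adam:
    """Adam with the standard bias correction (Kingma & Ba defaults)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1 - self.beta2) * p.grad ** 2
            p.value -= (self.lr * (m / b1t)
                        / (np.sqrt(v / b2t) + self.eps)).astype(DTYPE)
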