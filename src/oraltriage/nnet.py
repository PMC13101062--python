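"""A compact, deterministic NumPy neural-network engine.

Implements exactly the pieces the referral classifier needs — 2-D
convolution (im2col), ReLU, global average pooling, fully connected layers,
dropout, softmax cross-entropy, and Adam — with explicit forward/backward
passes.  Single-threaded NumPy arithmetic keeps full training runs
bit-reproducible on CPU from one integer seed, which the rehearsal
continual-learning contract (exact weight handoff between stages) relies on.

Tensors are NCHW float64 internally; parameters live in ``Param`` objects so
optimizers and checkpoint copies can address them by name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray

    @classmethod
    def zeros_like(cls, name: str, value: np.ndarray) -> "Param":
        return cls(name=name, value=value, grad=np.zeros_like(value))


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "linear"):
        self.w = Param.zeros_like(f"{name}.w", _he_init(rng, (n_in, n_out), n_in))
        self.b = Param.zeros_like(f"{name}.b", np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value.T


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout if self._mask is None else gout * self._mask


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # n,c,ho,wo,k,k
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return cols, ho, wo


class Conv2d(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 1,
        name: str = "conv",
    ):
        fan_in = c_in * k * k
        self.w = Param.zeros_like(f"{name}.w", _he_init(rng, (c_out, c_in, k, k), fan_in))
        self.b = Param.zeros_like(f"{name}.b", np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)  # c_out x (c k k)
        out = cols @ wmat.T + self.b.value
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        (n, c, h, w), cols, ho, wo = self._cache
        c_out = gout.shape[1]
        g = gout.transpose(0, 2, 3, 1).reshape(-1, c_out)  # (n ho wo) x c_out
        self.w.grad += (g.T @ cols).reshape(self.w.value.shape)
        self.b.grad += g.sum(axis=0)
        gcols = g @ self.w.value.reshape(c_out, -1)  # (n ho wo) x (c k k)
        # col2im: scatter-add each kernel offset back onto the padded input
        gx = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad))
        gcols = gcols.reshape(n, ho, wo, c, self.k, self.k).transpose(0, 3, 4, 5, 1, 2)
        for i in range(self.k):
            for j in range(self.k):
                gx[:, :, i : i + ho * self.stride : self.stride,
                   j : j + wo * self.stride : self.stride] += gcols[:, :, i, j]
        if self.pad:
            gx = gx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return gx


class GlobalAvgPool(Layer):
    """NCHW -> NC mean pool; the GradCAM hook point sits at its input."""

    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None], self._shape) / (h * w)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)
        #: set by backward(): gradient that arrived at each layer's output
        self.output_grads: list[np.ndarray | None] = [None] * len(self.layers)
        self.activations: list[np.ndarray | None] = [None] * len(self.layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            self.activations[i] = x
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            self.output_grads[i] = gout
            gout = self.layers[i].backward(gout)
        return gout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean (optionally class-weighted) CE; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[y]
    loss = float(-(w * np.log(p[np.arange(n), y] + 1e-12)).sum() / w.sum())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / w.sum())[:, None]
    return loss, dlogits


class Adam:
    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_weights(params: Sequence[Param]) -> dict[str, np.ndarray]:
    return {p.name: p.value.copy() for p in params}


def set_weights(params: Sequence[Param], weights: dict[str, np.ndarray]) -> None:
    for p in params:
        if p.name not in weights:
            raise KeyError(f"missing weight {p.name}")
        if p.value.shape != weights[p.name].shape:
            raise ValueError(f"shape mismatch for {p.name}")
        p.value[...] = weights[p.name]
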