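"""Minimal numpy CNN stack with explicit forward/backward passes.

Layers operate on NHWC float64 arrays. Every module caches what its
backward pass needs and, after a backward call, exposes the gradient it
received with respect to its *output* (``cached_dout``) — that is the hook
class-activation mapping uses to read d(score)/d(activation) at an
arbitrary convolutional layer without a separate autodiff graph.

Convolutions are im2col + matmul; sizes here are desk-scale (tens of
channels, <=128 px inputs), where this is fast enough on one CPU core.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2D",
    "DepthwiseConv2D",
    "ReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Residual",
    "Parallel",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: forward caches, backward returns grad w.r.t. input."""

    def params(self) -> list[Param]:
        return []

    def modules(self):
        """Depth-first iterator over self and all submodules."""
        yield self

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x already padded; -> (N, Ho, Wo, k, k, C)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # sliding_window_view yields (N, Ho, Wo, C, k, k)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))


class Conv2D(Module):
    """Same-padded 2-D convolution, stride 1, weight shape (k, k, cin, cout)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, name: str = "conv") -> None:
        self.k = k
        self.cin = cin
        self.cout = cout
        fan_in = k * k * cin
        self.w = Param(he_uniform(rng, (k, k, cin, cout), fan_in), f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self.name = name
        self.cached_out: np.ndarray | None = None
        self.cached_dout: np.ndarray | None = None
        self._cols: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = _im2col(_pad_same(x, self.k), self.k)  # (N,H,W,k,k,cin)
        self._cols = cols.reshape(n * h * w, -1)
        self._in_shape = x.shape
        out = self._cols @ self.w.value.reshape(-1, self.cout) + self.b.value
        out = out.reshape(n, h, w, self.cout)
        self.cached_out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.cached_dout = dout
        n, h, w, _ = self._in_shape
        dflat = dout.reshape(n * h * w, self.cout)
        self.w.grad += (self._cols.T @ dflat).reshape(self.w.value.shape)
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.w.value.reshape(-1, self.cout).T).reshape(
            n, h, w, self.k, self.k, self.cin
        )
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.cin))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class DepthwiseConv2D(Module):
    """Per-channel same-padded k x k convolution (the separable-conv motif)."""

    def __init__(self, c: int, k: int, rng: np.random.Generator, name: str = "dwconv") -> None:
        self.k = k
        self.c = c
        self.w = Param(he_uniform(rng, (c, k, k), k * k), f"{name}.w")
        self.b = Param(np.zeros(c), f"{name}.b")
        self.name = name
        self.cached_out: np.ndarray | None = None
        self.cached_dout: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        cols = _im2col(_pad_same(x, self.k), self.k)  # (N,H,W,k,k,C)
        self._cols = cols
        out = np.einsum("nhwklc,ckl->nhwc", cols, self.w.value) + self.b.value
        self.cached_out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.cached_dout = dout
        n, h, w, c = self._in_shape
        self.w.grad += np.einsum("nhwklc,nhwc->ckl", self._cols, dout)
        self.b.grad += dout.sum(axis=(0, 1, 2))
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dout * self.w.value[:, i, j]
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2D(Module):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h // 2, w // 2, c, 4)
        self._idx = np.argmax(xr, axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4))
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(n, h, w, c)


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(dout[:, None, None, :], (n, h, w, c)) / (h * w)


class Dense(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "dense") -> None:
        self.w = Param(he_uniform(rng, (cin, cout), cin), f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self.name = name

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class Sequential(Module):
    def __init__(self, layers: list[Module]) -> None:
        self.layers = list(layers)

    def modules(self):
        yield self
        for layer in self.layers:
            yield from layer.modules()

    def params(self) -> list[Param]:
        return [p for m in self.layers for p in m.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Residual(Module):
    """Additive skip connection: out = x + body(x); body must preserve shape."""

    def __init__(self, body: Module) -> None:
        self.body = body

    def modules(self):
        yield self
        yield from self.body.modules()

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.body.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout + self.body.backward(dout)


class Parallel(Module):
    """Inception-style block: run branches on the same input, concat channels."""

    def __init__(self, branches: list[Module]) -> None:
        self.branches = list(branches)

    def modules(self):
        yield self
        for b in self.branches:
            yield from b.modules()

    def params(self) -> list[Param]:
        return [p for b in self.branches for p in b.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [b.forward(x) for b in self.branches]
        self._splits = np.cumsum([o.shape[-1] for o in outs])[:-1]
        return np.concatenate(outs, axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        chunks = np.split(dout, self._splits, axis=-1)
        dx = self.branches[0].backward(chunks[0])
        for b, c in zip(self.branches[1:], chunks[1:]):
            dx = dx + b.backward(c)
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam with the standard (beta1=0.9, beta2=0.999, eps=1e-8) defaults."""

    def __init__(self, params: list[Param], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
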